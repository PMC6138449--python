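"""End-to-end experiment driver.

Ties the stages together — simulate → score questionnaire → denoise →
connectome → deconfound + family-aware predict → evaluate (→ permute) —
under a single serializable configuration, and runs the full analysis grid
(pipelines × sessions × models) on one cohort.  Every result bundle embeds
the configuration, the seed, and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import denoise as dn
from . import synth
from .connectome import average_fc, fc_matrix, stack_subjects
from .evaluation import permutation_test
from .neo import score_neoffi, superordinate_pca
from .prediction import ModelConfig, cv_runner, predict_cv

__all__ = ["ExperimentConfig", "run_experiment", "run_grid",
           "build_dataset", "confound_matrix", "FULL_CONFOUNDS",
           "MINIMAL_CONFOUNDS"]

FULL_CONFOUNDS = ["gender", "age", "handedness", "brain_size",
                  "motion_rest1", "motion_rest2", "recon_version", "gF"]
MINIMAL_CONFOUNDS = ["recon_version", "motion_rest1", "motion_rest2",
                     "brain_size"]

TARGETS = ("O", "C", "E", "A", "N", "alpha", "beta", "gF")
_SESSION_RUNS = {"REST1": ("REST1_LR", "REST1_RL"),
                 "REST2": ("REST2_LR", "REST2_RL"),
                 "REST12": synth.RUN_LABELS}


@dataclass(frozen=True)
class ExperimentConfig:
    pipeline: str = "A"
    session: str = "REST12"
    target: str = "gF"
    model: str = "univariate_pos"
    deconfound: str = "full"
    n_perm: int = 0
    n_subjects: int = 60
    n_parcels: int = 40
    n_timepoints: int = 300
    seed: int = 0
    filter_p: float = 0.01

    def __post_init__(self):
        if self.session not in _SESSION_RUNS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.deconfound not in ("full", "minimal", "none"):
            raise ValueError(f"unknown deconfound set {self.deconfound!r}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def confound_matrix(cohort: synth.Cohort, deconfound: str, target: str):
    """Confound design for the configured set; the predicted score itself
    never appears in its own confound set."""
    if deconfound == "none":
        return None, []
    names = list(FULL_CONFOUNDS if deconfound == "full" else MINIMAL_CONFOUNDS)
    if target == "gF" and "gF" in names:
        names.remove("gF")
    return cohort.table[names].to_numpy(dtype=float), names


@dataclass
class Dataset:
    """A simulated cohort with scored traits and session edge matrices."""

    cohort: synth.Cohort
    truth: synth.GroundTruth
    traits: "object"
    superordinate: "object"
    edges: dict          # (pipeline, session) -> EdgeMatrix
    exclusion_log: "object" = None

    def scores(self, target: str) -> np.ndarray:
        if target == "gF":
            return self.cohort.table["gF"].to_numpy(dtype=float)
        if target in ("alpha", "beta"):
            return self.superordinate.scores[target].to_numpy()
        return self.traits[target].to_numpy(dtype=float)


def build_dataset(cfg: ExperimentConfig, pipelines=None,
                  sessions=None, apply_inclusion: bool = True) -> Dataset:
    """Simulate a cohort and produce denoised edge matrices.

    Runs are generated per subject, denoised with each requested pipeline
    (pipeline C consumes artifact-free, FIX-like input), correlated over
    retained volumes, Fisher-z averaged into sessions, and stacked.
    """
    pipelines = pipelines or [cfg.pipeline]
    sessions = sessions or [cfg.session]
    spec = synth.CohortSpec(n_subjects=cfg.n_subjects,
                            n_families=max(1, cfg.n_subjects // 2),
                            n_parcels=cfg.n_parcels, seed=cfg.seed)
    cohort, truth = synth.generate_cohort(spec)
    if apply_inclusion:
        cohort, log = synth.apply_inclusion_criteria(cohort)
    else:
        log = None
    items = synth.generate_item_responses(cohort, spec.trait_model,
                                          seed=cfg.seed)
    traits = score_neoffi(items)
    superord = superordinate_pca(traits)

    run_labels = sorted({lbl for s in sessions for lbl in _SESSION_RUNS[s]})
    edges = {}
    per_pipeline_fc = {p: {lbl: [] for lbl in run_labels} for p in pipelines}
    for lbl in run_labels:
        clean_runs = synth.generate_run_timeseries(
            cohort, truth, lbl, n_timepoints=cfg.n_timepoints)
        fix_runs = (synth.generate_run_timeseries(
            cohort, truth, lbl, n_timepoints=cfg.n_timepoints, fix_like=True)
            if "C" in pipelines else None)
        for p in pipelines:
            cfg_dn = dn.DenoiseConfig(pipeline=p)
            source = fix_runs if p == "C" else clean_runs
            for run in source:
                cleaned = dn.denoise(run, cfg_dn)
                per_pipeline_fc[p][lbl].append(fc_matrix(cleaned))
    for p in pipelines:
        for s in sessions:
            mats = []
            by_subj: dict[str, list] = {}
            for lbl in _SESSION_RUNS[s]:
                for m in per_pipeline_fc[p][lbl]:
                    by_subj.setdefault(m.subject_id, []).append(m)
            for sid in cohort.subject_ids:
                mats.append(average_fc(by_subj[sid], session_label=s))
            edges[(p, s)] = stack_subjects(mats, cohort.subject_ids, s)
    return Dataset(cohort=cohort, truth=truth, traits=traits,
                   superordinate=superord, edges=edges, exclusion_log=log)


def run_experiment(cfg: ExperimentConfig,
                   dataset: Dataset | None = None) -> dict:
    """Run one analysis cell and return a serializable result bundle."""
    ds = dataset or build_dataset(cfg)
    x = ds.edges[(cfg.pipeline, cfg.session)]
    y = ds.scores(cfg.target)
    conf, names = confound_matrix(ds.cohort, cfg.deconfound, cfg.target)
    mc = ModelConfig(model=cfg.model, filter_p=cfg.filter_p,
                     deconfound_set=cfg.deconfound)
    res = predict_cv(x, y, conf, ds.cohort.family_ids, mc, seed=cfg.seed)
    metrics = res.metrics()
    bundle = {
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "confound_names": names,
        "n_subjects": ds.cohort.n,
        "metrics": metrics.as_dict(),
        "observed": res.observed.tolist(),
        "predicted": res.predicted.tolist(),
        "fold_id": res.fold_id.tolist(),
        "per_fold": [{k: v for k, v in info.items()
                      if k in ("fold", "n_pos", "n_neg", "n_selected",
                               "alpha", "fallback")}
                     for info in res.fold_info],
    }
    if cfg.n_perm > 0:
        runner = cv_runner(x, conf, ds.cohort.family_ids, mc, seed=cfg.seed)
        null = permutation_test(runner, y, n_perm=cfg.n_perm, seed=cfg.seed)
        bundle["permutation"] = null.as_dict()
    return bundle


def run_grid(base: ExperimentConfig,
             pipelines=("A", "B", "C"),
             sessions=("REST1", "REST2"),
             models=("univariate_pos", "univariate_neg", "elastic_net")
             ) -> list[dict]:
    """The pipelines × sessions × models analysis grid on one cohort."""
    ds = build_dataset(base, pipelines=list(pipelines),
                       sessions=list(sessions))
    out = []
    for p in pipelines:
        for s in sessions:
            for m in models:
                cfg = ExperimentConfig(**{**asdict(base), "pipeline": p,
                                          "session": s, "model": m})
                out.append(run_experiment(cfg, dataset=ds))
    return out
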