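"""Synthetic cohorts with known connectome and trait structure.

The generator emulates the statistical structure a resting-state
prediction study relies on, with every latent quantity exposed as ground
truth so that downstream stages (denoising, connectome construction,
reliability, family-aware prediction, permutation inference) can be tested
for parameter recovery without any imaging data:

* a cohort with **family structure** (latent traits share a within-family
  component with a configurable correlation);
* five **latent personality traits** drawn from a configurable
  intercorrelation matrix, plus demographic/technical confounds that are
  correlated with the traits;
* 60-item Likert **questionnaire responses** generated by thresholding a
  Gaussian item propensity (loading · trait + noise) at equal-probability
  cut points, so standard sum-scoring inverts the generator;
* per-run multichannel **time series** whose parcel channels are a linear
  mixing of group, family, subject-stable, and session latent sources
  (plus white noise), making each subject's target FC matrix analytically
  known; trait- and confound-linked edge sets are planted with a chosen
  cross-subject correlation; motion parameters, a framewise-displacement
  trace, tissue reference channels, and optional drift/motion/spike
  artifacts are attached.

The subject-stable share of FC variance (``fingerprint_share``) and the
within-family share (``familial_fc_share``) are explicit dials, so
identification-rate and family-leakage phenomena can be produced at will.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import n_edges
from .neo import FACTORS, ITEM_CODING
from .runs import RUN_LABELS, RunTimeSeries

__all__ = [
    "LatentTraitModel",
    "CohortSpec",
    "Cohort",
    "GroundTruth",
    "InclusionCriteria",
    "generate_cohort",
    "generate_item_responses",
    "generate_run_timeseries",
    "apply_inclusion_criteria",
    "simulate_edges",
    "DEFAULT_TRAIT_CORR",
]

#: Trait intercorrelations emulating a typical questionnaire sample:
#: Neuroticism anticorrelated with C/E/A, those three mutually positive,
#: Openness only weakly related to the rest.
DEFAULT_TRAIT_CORR = np.array([
    #  O     C     E     A     N
    [1.00, 0.10, 0.15, 0.05, -0.10],
    [0.10, 1.00, 0.25, 0.22, -0.41],
    [0.15, 0.25, 1.00, 0.30, -0.34],
    [0.05, 0.22, 0.30, 1.00, -0.28],
    [-0.10, -0.41, -0.34, -0.28, 1.00],
])

CONFOUND_NAMES = ("gender", "age", "handedness", "brain_size",
                  "motion_rest1", "motion_rest2", "recon_version", "gF")

#: modest trait loadings of each confound, emulating the usual pattern of
#: gender/age/intelligence correlates of questionnaire factors
DEFAULT_CONFOUND_TRAIT_LOADINGS: dict[str, dict[str, float]] = {
    "gender": {"O": -0.15, "C": 0.15, "A": 0.20, "N": 0.15},
    "age": {"O": -0.10, "A": 0.10},
    "handedness": {},
    "brain_size": {"O": 0.10, "C": -0.10, "A": -0.10, "N": -0.10},
    "recon_version": {"O": 0.08},
    "gF": {"O": 0.25, "C": -0.15, "E": -0.10, "N": -0.15},
}


@dataclass(frozen=True)
class LatentTraitModel:
    n_traits: int = 5
    trait_intercorrelation: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    item_loading: float = 0.6
    item_noise_sd: float = 1.0
    signal_edges: dict[str, np.ndarray] | None = None
    signal_effect: dict[str, float] = field(default_factory=dict)
    n_signal_edges: int = 100

    def validate(self):
        c = np.asarray(self.trait_intercorrelation, dtype=float)
        if c.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_intercorrelation has wrong shape")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("trait_intercorrelation must be symmetric with "
                             "unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("trait_intercorrelation is not positive "
                             "semi-definite")
        for t, e in self.signal_effect.items():
            if not 0 <= e < 1:
                raise ValueError(f"signal_effect[{t}] must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 100
    n_families: int = 45
    family_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.45, 3: 0.25, 4: 0.05})
    trait_model: LatentTraitModel = field(default_factory=LatentTraitModel)
    confound_trait_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_CONFOUND_TRAIT_LOADINGS.items()})
    confound_effects: dict[str, tuple[np.ndarray, float]] = field(
        default_factory=dict)
    familial_trait_corr: float = 0.3
    fingerprint_share: float = 0.35
    familial_fc_share: float = 0.15
    session_share: float = 0.15
    white_noise_share: float = 0.15
    run_innovation_share: float = 1.0
    n_parcels: int = 60
    mmse_low_prob: float = 0.01
    incomplete_prob: float = 0.02
    seed: int = 0

    def validate(self):
        if self.n_families > self.n_subjects:
            raise ValueError("n_families cannot exceed n_subjects")
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")
        for name in ("familial_trait_corr", "fingerprint_share",
                     "familial_fc_share", "session_share",
                     "white_noise_share", "run_innovation_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if (self.fingerprint_share + self.familial_fc_share
                + self.session_share + self.white_noise_share) > 1 + 1e-12:
            raise ValueError("FC variance shares sum to more than 1")
        if any(s < 1 for s in self.family_size_dist):
            raise ValueError("family sizes must be >= 1")
        self.trait_model.validate()

    @property
    def group_share(self) -> float:
        return max(0.0, 1.0 - self.fingerprint_share - self.familial_fc_share
                   - self.session_share - self.white_noise_share)


@dataclass
class Cohort:
    """Subject roster: ids, family ids, confounds, latent traits, QC fields."""

    table: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def family_ids(self) -> np.ndarray:
        return self.table["family_id"].to_numpy()

    def latent_traits(self) -> np.ndarray:
        return self.table[[f"latent_{f}" for f in FACTORS]].to_numpy()

    def confounds(self, names=CONFOUND_NAMES) -> pd.DataFrame:
        return self.table[list(names)]


@dataclass
class GroundTruth:
    """Everything needed to reconstruct each subject's target FC exactly."""

    spec: CohortSpec
    group_corr: np.ndarray                  # P x P
    family_corr: dict[str, np.ndarray]      # per family
    subject_corr: dict[str, np.ndarray]     # per subject (stable component)
    signal_edges: dict[str, np.ndarray]     # trait -> upper-tri edge indices
    signal_gamma: dict[str, np.ndarray]     # trait -> per-edge slope
    confound_edges: dict[str, tuple[np.ndarray, np.ndarray]]
    trait_z: pd.DataFrame                   # standardized latent traits
    confound_z: pd.DataFrame                # standardized confound values

    def _session_corr(self, subject_index: int, session: int) -> np.ndarray:
        rng = np.random.default_rng(
            [self.spec.seed, 7001, subject_index, session])
        return _random_corr(self.spec.n_parcels, rng)

    def target_correlation(self, subject_id: str, session: int,
                           family_id: str, subject_index: int) -> np.ndarray:
        """Target parcel-correlation matrix for one subject-session."""
        s = self.spec
        c = (s.group_share * self.group_corr
             + s.familial_fc_share * self.family_corr[family_id]
             + s.fingerprint_share * self.subject_corr[subject_id]
             + s.session_share * self._session_corr(subject_index, session))
        c = c + s.white_noise_share * np.eye(s.n_parcels)
        iu = np.triu_indices(s.n_parcels, k=1)
        delta = np.zeros(iu[0].size)
        for t, idx in self.signal_edges.items():
            z = self.trait_z.iloc[subject_index][t]
            delta[idx] += self.signal_gamma[t] * np.clip(z, -2.5, 2.5)
        for name, (idx, gamma) in self.confound_edges.items():
            z = self.confound_z.iloc[subject_index][name]
            delta[idx] += gamma * np.clip(z, -2.5, 2.5)
        full = np.zeros_like(c)
        full[iu] = delta
        c = c + full + full.T
        return _nearest_corr(c)


def _random_corr(p: int, rng: np.random.Generator,
                 rank: int | None = None) -> np.ndarray:
    """Random correlation-scale PSD matrix from a low-rank factor model."""
    k = rank or max(2, p // 2)
    a = rng.standard_normal((p, k))
    c = a @ a.T / k
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _nearest_corr(c: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues at a small floor and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() >= floor:
        return c
    w = np.clip(w, floor, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _family_sizes(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    sizes = np.array(sorted(spec.family_size_dist), dtype=int)
    probs = np.array([spec.family_size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(sizes, size=spec.n_families, p=probs)
    # rescale to exactly n_subjects, keeping every family at size >= 1
    diff = spec.n_subjects - int(draw.sum())
    order = rng.permutation(spec.n_families)
    i = 0
    while diff != 0:
        j = order[i % spec.n_families]
        if diff > 0:
            draw[j] += 1
            diff -= 1
        elif draw[j] > 1:
            draw[j] -= 1
            diff += 1
        i += 1
        if i > 100 * spec.n_families:
            raise ValueError("cannot partition subjects into the requested "
                             "families")
    return draw


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its FC ground truth. Deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    sizes = _family_sizes(spec, rng)
    family_of = np.repeat(np.arange(spec.n_families), sizes)
    family_ids = [f"F{f:04d}" for f in family_of]
    subject_ids = [f"S{i:05d}" for i in range(spec.n_subjects)]

    # latent traits: shared family component + individual component
    corr = np.asarray(spec.trait_model.trait_intercorrelation, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    fam_eff = rng.standard_normal((spec.n_families, 5)) @ chol.T
    ind_eff = rng.standard_normal((spec.n_subjects, 5)) @ chol.T
    rho = spec.familial_trait_corr
    traits = np.sqrt(rho) * fam_eff[family_of] + np.sqrt(1 - rho) * ind_eff

    tz = (traits - traits.mean(axis=0)) / traits.std(axis=0)
    trait_z = pd.DataFrame(tz, columns=list(FACTORS))

    table = pd.DataFrame({"subject_id": subject_ids, "family_id": family_ids})
    for j, f in enumerate(FACTORS):
        table[f"latent_{f}"] = traits[:, j]

    # confounds: trait-loaded latent + independent noise, then transformed
    conf_latent = {}
    for name in CONFOUND_NAMES:
        loadings = spec.confound_trait_loadings.get(name, {})
        mix = np.zeros(spec.n_subjects)
        var = 0.0
        for f, w in loadings.items():
            mix += w * tz[:, FACTORS.index(f)]
            var += w ** 2
        noise_sd = np.sqrt(max(1.0 - var, 0.05))
        conf_latent[name] = mix + noise_sd * rng.standard_normal(spec.n_subjects)
    table["gender"] = (conf_latent["gender"] > 0).astype(int)
    table["age"] = np.clip(28.6 + 3.7 * conf_latent["age"], 22, 36).round(1)
    table["handedness"] = np.clip(
        65 + 40 * conf_latent["handedness"], -100, 100).round(0)
    table["brain_size"] = (1.15e6 + 1.1e5 * conf_latent["brain_size"]).round(0)
    table["recon_version"] = (conf_latent["recon_version"] > 0.3).astype(int)
    table["gF"] = np.clip(16 + 4 * conf_latent["gF"], 3, 24).round(0)

    # per-run motion: lognormal subject propensity, run-level jitter
    propensity = np.exp(np.log(0.065) + 0.35 * rng.standard_normal(spec.n_subjects))
    run_rms = propensity[:, None] * np.exp(
        0.2 * rng.standard_normal((spec.n_subjects, 4)))
    for r in range(4):
        table[f"run_motion_rms_{r + 1}"] = run_rms[:, r]
    table["motion_rest1"] = run_rms[:, :2].mean(axis=1)
    table["motion_rest2"] = run_rms[:, 2:].mean(axis=1)

    table["mmse"] = np.where(
        rng.random(spec.n_subjects) < spec.mmse_low_prob,
        rng.integers(20, 27, spec.n_subjects),
        30 - rng.binomial(3, 0.12, spec.n_subjects))
    table["neuropsych_complete"] = rng.random(spec.n_subjects) >= spec.incomplete_prob
    table["fmri_complete"] = rng.random(spec.n_subjects) >= spec.incomplete_prob

    conf_z = {}
    for name in CONFOUND_NAMES:
        v = table[name].to_numpy(dtype=float)
        sd = v.std()
        conf_z[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    confound_z = pd.DataFrame(conf_z)

    # FC components
    rng_fc = np.random.default_rng([spec.seed, 2])
    group_corr = _random_corr(spec.n_parcels, rng_fc)
    family_corr = {f"F{f:04d}": _random_corr(spec.n_parcels, rng_fc)
                   for f in range(spec.n_families)}
    subject_corr = {sid: _random_corr(spec.n_parcels, rng_fc)
                    for sid in subject_ids}

    # planted trait-linked edges, calibrated so the cross-subject correlation
    # between the target edge value and the trait equals the requested effect
    tm = spec.trait_model
    ne = n_edges(spec.n_parcels)
    rng_edges = np.random.default_rng([spec.seed, 3])
    signal_edges: dict[str, np.ndarray] = {}
    signal_gamma: dict[str, np.ndarray] = {}
    base = _base_edge_values(spec, group_corr, family_corr, subject_corr,
                             family_ids, subject_ids)
    for t, effect in tm.signal_effect.items():
        if effect <= 0:
            continue
        if tm.signal_edges and t in tm.signal_edges:
            idx = np.asarray(tm.signal_edges[t], dtype=int)
        else:
            idx = rng_edges.choice(ne, size=min(tm.n_signal_edges, ne),
                                   replace=False)
        sigma_e = base[:, idx].std(axis=0)
        sigma_e = np.maximum(sigma_e, 0.01)
        signal_edges[t] = idx
        signal_gamma[t] = effect / np.sqrt(1 - effect ** 2) * sigma_e
    confound_edges = {}
    for name, (idx, effect) in spec.confound_effects.items():
        idx = np.asarray(idx, dtype=int)
        sigma_e = np.maximum(base[:, idx].std(axis=0), 0.01)
        confound_edges[name] = (idx, effect / np.sqrt(1 - effect ** 2) * sigma_e)

    truth = GroundTruth(spec=spec, group_corr=group_corr,
                        family_corr=family_corr, subject_corr=subject_corr,
                        signal_edges=signal_edges, signal_gamma=signal_gamma,
                        confound_edges=confound_edges, trait_z=trait_z,
                        confound_z=confound_z)
    return Cohort(table=table), truth


def _base_edge_values(spec, group_corr, family_corr, subject_corr,
                      family_ids, subject_ids) -> np.ndarray:
    """Stable (session-averaged) target edge values without planted signal."""
    iu = np.triu_indices(spec.n_parcels, k=1)
    rows = []
    for sid, fid in zip(subject_ids, family_ids):
        c = (spec.group_share * group_corr
             + spec.familial_fc_share * family_corr[fid]
             + spec.fingerprint_share * subject_corr[sid])
        rows.append(c[iu])
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# serialization: every stochastic component regenerates deterministically
# from the spec, so the spec (plus version tags) IS the ground truth record

def spec_to_dict(spec: CohortSpec) -> dict:
    tm = spec.trait_model
    return {
        "n_subjects": spec.n_subjects, "n_families": spec.n_families,
        "family_size_dist": {str(k): v for k, v in
                             spec.family_size_dist.items()},
        "trait_model": {
            "n_traits": tm.n_traits,
            "trait_intercorrelation":
                np.asarray(tm.trait_intercorrelation).tolist(),
            "item_loading": tm.item_loading,
            "item_noise_sd": tm.item_noise_sd,
            "signal_edges": ({k: np.asarray(v).tolist() for k, v in
                              tm.signal_edges.items()}
                             if tm.signal_edges else None),
            "signal_effect": dict(tm.signal_effect),
            "n_signal_edges": tm.n_signal_edges,
        },
        "confound_trait_loadings": {k: dict(v) for k, v in
                                    spec.confound_trait_loadings.items()},
        "confound_effects": {k: [np.asarray(i).tolist(), e] for k, (i, e) in
                             spec.confound_effects.items()},
        "familial_trait_corr": spec.familial_trait_corr,
        "fingerprint_share": spec.fingerprint_share,
        "familial_fc_share": spec.familial_fc_share,
        "session_share": spec.session_share,
        "white_noise_share": spec.white_noise_share,
        "run_innovation_share": spec.run_innovation_share,
        "n_parcels": spec.n_parcels,
        "mmse_low_prob": spec.mmse_low_prob,
        "incomplete_prob": spec.incomplete_prob,
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> CohortSpec:
    tm = d["trait_model"]
    model = LatentTraitModel(
        n_traits=tm["n_traits"],
        trait_intercorrelation=np.asarray(tm["trait_intercorrelation"]),
        item_loading=tm["item_loading"], item_noise_sd=tm["item_noise_sd"],
        signal_edges=({k: np.asarray(v, dtype=int) for k, v in
                       tm["signal_edges"].items()}
                      if tm.get("signal_edges") else None),
        signal_effect=dict(tm["signal_effect"]),
        n_signal_edges=tm["n_signal_edges"])
    return CohortSpec(
        n_subjects=d["n_subjects"], n_families=d["n_families"],
        family_size_dist={int(k): v for k, v in
                          d["family_size_dist"].items()},
        trait_model=model,
        confound_trait_loadings={k: dict(v) for k, v in
                                 d["confound_trait_loadings"].items()},
        confound_effects={k: (np.asarray(i, dtype=int), e) for k, (i, e) in
                          d["confound_effects"].items()},
        familial_trait_corr=d["familial_trait_corr"],
        fingerprint_share=d["fingerprint_share"],
        familial_fc_share=d["familial_fc_share"],
        session_share=d["session_share"],
        white_noise_share=d["white_noise_share"],
        run_innovation_share=d["run_innovation_share"],
        n_parcels=d["n_parcels"], mmse_low_prob=d["mmse_low_prob"],
        incomplete_prob=d["incomplete_prob"], seed=d["seed"])


# ---------------------------------------------------------------------------
# questionnaire responses

def generate_item_responses(cohort: Cohort,
                            model: LatentTraitModel | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """Likert item responses consistent with the published scoring map.

    Each item's propensity is ``sign · loading · trait + N(0, noise_sd²)``
    (the sign matching the reverse-coding of that item); the propensity is
    discretized at equal-probability Gaussian cut points into {0..4}.
    Summing the reverse-corrected items therefore recovers the latent trait
    ordering, exactly so in the noiseless limit.
    """
    model = model or LatentTraitModel()
    rng = np.random.default_rng(
        [seed if seed is not None else 12345, 4])
    z = cohort.latent_traits()
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    out = pd.DataFrame({"subject_id": cohort.subject_ids})
    sd_total = np.sqrt(model.item_loading ** 2 + model.item_noise_sd ** 2)
    cuts = stats.norm.ppf([0.2, 0.4, 0.6, 0.8]) * max(sd_total, 1e-12)
    resp = np.empty((cohort.n, 60), dtype=int)
    for f_idx, factor in enumerate(FACTORS):
        for item in ITEM_CODING[factor]:
            sign = -1 if item < 0 else 1
            prop = (sign * model.item_loading * z[:, f_idx]
                    + model.item_noise_sd * rng.standard_normal(cohort.n))
            resp[:, abs(item) - 1] = np.searchsorted(cuts, prop)
    for i in range(60):
        out[f"item_{i + 1}"] = resp[:, i]
    return out


# ---------------------------------------------------------------------------
# time series

@dataclass(frozen=True)
class ArtifactModel:
    """Amplitudes of injected artifacts, relative to unit signal SD."""

    drift: float = 0.5
    motion_coupling: float = 0.5
    spike_prob: float = 0.003
    spike_amp: float = 4.0


_SESSION_OF = {"REST1_LR": 1, "REST1_RL": 1, "REST2_LR": 2, "REST2_RL": 2}
N_WM, N_CSF = 6, 3


def generate_run_timeseries(cohort: Cohort, truth: GroundTruth,
                            run_label: str, n_parcels: int | None = None,
                            n_timepoints: int = 1200, tr_s: float = 0.72,
                            artifacts: ArtifactModel | None = None,
                            fix_like: bool = False,
                            subjects: list[str] | None = None
                            ) -> list[RunTimeSeries]:
    """Generate one labeled run for every (or selected) cohort subject.

    Parcel channels are Gaussian with the subject-session target
    correlation from the ground truth; tissue reference channels (WM, CSF,
    global), six motion parameters and an FD trace are attached.  Unless
    ``fix_like`` is set, drift and motion-coupled artifacts (plus rare
    spikes) contaminate the signal channels, giving the denoising
    pipelines something to remove.
    """
    if run_label not in RUN_LABELS:
        raise ValueError(f"unknown run label {run_label!r}")
    spec = truth.spec
    if n_parcels is None:
        n_parcels = spec.n_parcels
    if n_parcels != spec.n_parcels:
        raise ValueError("n_parcels must match the cohort's ground truth")
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    if n_timepoints < 8:
        raise ValueError("too few time points")
    art = ArtifactModel(0.0, 0.0, 0.0, 0.0) if fix_like else (
        artifacts or ArtifactModel())
    session = _SESSION_OF[run_label]
    run_idx = RUN_LABELS.index(run_label)
    wanted = subjects or cohort.subject_ids
    pos = {sid: i for i, sid in enumerate(cohort.subject_ids)}
    runs = []
    for sid in wanted:
        i = pos[sid]
        fid = cohort.table["family_id"].iloc[i]
        c = truth.target_correlation(sid, session, fid, i)
        chol = np.linalg.cholesky(c + 1e-10 * np.eye(n_parcels))
        base_rng = np.random.default_rng([spec.seed, 5, i])
        z_base = base_rng.standard_normal((n_timepoints, n_parcels))
        run_rng = np.random.default_rng([spec.seed, 6, i, run_idx])
        eta = spec.run_innovation_share
        z = (np.sqrt(1 - eta) * z_base
             + np.sqrt(eta) * run_rng.standard_normal((n_timepoints, n_parcels)))
        parcels = z @ chol.T

        motion, fd = _motion_trace(
            run_rng, n_timepoints,
            cohort.table[f"run_motion_rms_{run_idx + 1}"].iloc[i])
        parcels, wm, csf = _attach_noise_channels(
            run_rng, parcels, fd, art, n_timepoints)
        glob = parcels.mean(axis=1, keepdims=True) \
            + 0.1 * run_rng.standard_normal((n_timepoints, 1))
        channels = np.column_stack([parcels, wm, csf, glob])
        roles = (["parcel"] * n_parcels + ["WM"] * N_WM + ["CSF"] * N_CSF
                 + ["global"])
        runs.append(RunTimeSeries(subject_id=sid, run_label=run_label,
                                  channels=channels, channel_roles=roles,
                                  motion_params=motion, fd=fd, tr_s=tr_s))
    return runs


def _motion_trace(rng, t: int, target_mean_fd: float):
    """Six realignment parameters (random-walk) scaled so the mean FD over
    the run matches the subject's per-run motion summary."""
    steps = rng.standard_normal((t, 6)) * 0.01
    steps[0] = 0
    params = np.cumsum(steps, axis=0)
    d = np.abs(np.diff(params, axis=0))
    fd_raw = np.zeros(t)
    fd_raw[1:] = d[:, :3].sum(axis=1) + 50.0 * d[:, 3:].sum(axis=1)
    mean_fd = fd_raw[1:].mean()
    scale = target_mean_fd / mean_fd if mean_fd > 0 else 1.0
    params *= scale
    fd = fd_raw * scale
    return params, fd


def _attach_noise_channels(rng, parcels, fd, art: ArtifactModel, t: int):
    """Inject drift/motion/spike artifacts and build WM/CSF channels."""
    grid = np.linspace(-1, 1, t)
    drift_basis = np.vander(grid, 4, increasing=True)[:, 1:]  # t, t^2, t^3
    fd_z = (fd - fd.mean()) / (fd.std() + 1e-12)

    def contaminate(x, n_ch):
        if art.drift > 0:
            coefs = rng.standard_normal((3, n_ch))
            x = x + art.drift * drift_basis @ coefs
        if art.motion_coupling > 0:
            load = rng.standard_normal(n_ch) * art.motion_coupling
            x = x + np.outer(fd_z, load)
        if art.spike_prob > 0:
            spikes = rng.random(t) < art.spike_prob
            x = x + np.outer(spikes, rng.standard_normal(n_ch) * art.spike_amp)
        return x

    parcels = contaminate(parcels, parcels.shape[1])
    wm_latent = rng.standard_normal((t, 1))
    csf_latent = rng.standard_normal((t, 1))
    wm = 0.8 * wm_latent + 0.6 * rng.standard_normal((t, N_WM))
    csf = 0.8 * csf_latent + 0.6 * rng.standard_normal((t, N_CSF))
    wm = contaminate(wm, N_WM)
    csf = contaminate(csf, N_CSF)
    return parcels, wm, csf


# ---------------------------------------------------------------------------
# inclusion criteria

@dataclass(frozen=True)
class InclusionCriteria:
    mmse_max_excluded: int = 26      # scores <= this are excluded
    motion_rms_max_mm: float = 0.15  # any run above this excludes


def apply_inclusion_criteria(cohort: Cohort,
                             criteria: InclusionCriteria | None = None
                             ) -> tuple[Cohort, pd.DataFrame]:
    """Filter a cohort in the fixed order completeness → MMSE → fMRI
    completeness → motion; return the kept cohort and an exclusion log.
    """
    criteria = criteria or InclusionCriteria()
    t = cohort.table
    required = ["mmse", "neuropsych_complete", "fmri_complete"] + [
        f"run_motion_rms_{r}" for r in range(1, 5)]
    for col in required:
        if col not in t.columns:
            raise ValueError(f"missing required column: {col}")
    reasons = {}
    keep = pd.Series(True, index=t.index)
    steps = [
        ("completeness", ~t["neuropsych_complete"]),
        ("MMSE", t["mmse"] <= criteria.mmse_max_excluded),
        ("fmri_completeness", ~t["fmri_complete"]),
        ("motion", (t[[f"run_motion_rms_{r}" for r in range(1, 5)]]
                    > criteria.motion_rms_max_mm).any(axis=1)),
    ]
    for reason, hit in steps:
        newly = keep & hit
        for i in t.index[newly]:
            reasons[t.loc[i, "subject_id"]] = reason
        keep &= ~hit
    log = pd.DataFrame({"subject_id": list(reasons), "reason":
                        list(reasons.values())})
    return Cohort(table=t[keep].reset_index(drop=True)), log


# ---------------------------------------------------------------------------
# fast path: session edge matrices without artifact/denoise machinery

def simulate_edges(spec: CohortSpec, n_timepoints: int = 300,
                   sessions: tuple[int, ...] = (1,),
                   runs_per_session: int = 2):
    """Cohort plus empirical session EdgeMatrix(es) from clean time series.

    Convenience path for statistical experiments that do not exercise the
    denoising operators: for each subject and session, `runs_per_session`
    clean runs are sampled from the target correlation, correlated,
    Fisher-z transformed and averaged.  Returns ``(cohort, truth,
    {session: EdgeMatrix})``.
    """
    from .connectome import EdgeMatrix

    cohort, truth = generate_cohort(spec)
    p = spec.n_parcels
    iu = np.triu_indices(p, k=1)
    cap = 1.0 - 1e-7
    out = {}
    for sess in sessions:
        rows = np.empty((cohort.n, iu[0].size))
        for i, sid in enumerate(cohort.subject_ids):
            fid = cohort.table["family_id"].iloc[i]
            c = truth.target_correlation(sid, sess, fid, i)
            chol = np.linalg.cholesky(c + 1e-10 * np.eye(p))
            zsum = np.zeros(iu[0].size)
            for r in range(runs_per_session):
                rng = np.random.default_rng([spec.seed, 8, i, sess, r])
                x = rng.standard_normal((n_timepoints, p)) @ chol.T
                cc = np.corrcoef(x, rowvar=False)
                zsum += np.arctanh(np.clip(cc[iu], -cap, cap))
            rows[i] = zsum / runs_per_session
        out[sess] = EdgeMatrix(values=rows, subject_ids=cohort.subject_ids,
                               session_label=f"REST{sess}", n_parcels=p)
    return cohort, truth, out
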