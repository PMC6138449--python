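"""Plain-text interchange: TSV tables and JSON results.

All file formats are delimited text so that datasets remain diffable and
platform-neutral: a subject roster (``subjects.tsv``), a 60-item response
table (``items.tsv``), per-subject run tables (``run_<label>.tsv``, time ×
channels with the channel role encoded in each column name), edge matrices
(subjects × edges with parcel-pair column headers), and JSON for ground
truth and result bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import EdgeMatrix, n_edges
from .runs import RunTimeSeries
from .synth import Cohort

__all__ = [
    "write_cohort", "read_cohort", "write_items", "read_items",
    "write_run", "read_run", "write_edges", "read_edges",
    "write_json", "read_json", "validate_tables",
]


def write_cohort(cohort: Cohort, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> Cohort:
    return Cohort(table=pd.read_csv(path, sep="\t"))


def write_items(items: pd.DataFrame, path) -> None:
    items.to_csv(path, sep="\t", index=False)


def read_items(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _run_columns(run: RunTimeSeries) -> list[str]:
    counts: dict[str, int] = {}
    cols = []
    for role in run.channel_roles:
        k = counts.get(role, 0)
        counts[role] = k + 1
        cols.append(f"{role}.{k}")
    return cols


def write_run(run: RunTimeSeries, path) -> None:
    df = pd.DataFrame(run.channels, columns=_run_columns(run))
    for j in range(6):
        df[f"motion.{j}"] = run.motion_params[:, j]
    df["FD"] = run.fd
    df["censor"] = run.censor_mask.astype(int)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={run.subject_id} run_label={run.run_label} "
                 f"tr_s={run.tr_s}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_run(path) -> RunTimeSeries:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    chan_cols = [c for c in df.columns
                 if c.split(".")[0] in ("parcel", "WM", "CSF", "global")]
    roles = [c.split(".")[0] for c in chan_cols]
    return RunTimeSeries(
        subject_id=meta["subject_id"], run_label=meta["run_label"],
        channels=df[chan_cols].to_numpy(),
        channel_roles=roles,
        motion_params=df[[f"motion.{j}" for j in range(6)]].to_numpy(),
        fd=df["FD"].to_numpy(), tr_s=float(meta["tr_s"]),
        censor_mask=df["censor"].to_numpy().astype(bool))


def write_edges(edges: EdgeMatrix, path) -> None:
    iu = np.triu_indices(edges.n_parcels, k=1)
    cols = [f"e{i}_{j}" for i, j in zip(*iu)]
    df = pd.DataFrame(edges.values, columns=cols)
    df.insert(0, "subject_id", edges.subject_ids)
    with open(path, "w") as fh:
        fh.write(f"# session={edges.session_label} "
                 f"n_parcels={edges.n_parcels}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_edges(path) -> EdgeMatrix:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    return EdgeMatrix(
        values=df.drop(columns="subject_id").to_numpy(),
        subject_ids=df["subject_id"].astype(str).tolist(),
        session_label=meta["session"], n_parcels=int(meta["n_parcels"]))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())


def validate_tables(subjects_path=None, items_path=None,
                    edges_path=None) -> list[str]:
    """Schema and cross-reference checks; returns a list of problems."""
    report: list[str] = []
    roster = None
    if subjects_path is not None:
        roster = pd.read_csv(subjects_path, sep="\t")
        for col in ("subject_id", "family_id", "mmse"):
            if col not in roster.columns:
                report.append(f"subjects: missing column {col!r}")
        if roster is not None and roster.isna().any().any():
            bad = roster.columns[roster.isna().any()].tolist()
            report.append(f"subjects: missing values in {bad}")
    if items_path is not None:
        items = pd.read_csv(items_path, sep="\t")
        item_cols = [f"item_{i}" for i in range(1, 61)]
        missing = [c for c in item_cols if c not in items.columns]
        if missing:
            report.append(f"items: missing columns {missing[:3]}...")
        else:
            vals = items[item_cols].to_numpy()
            if not np.isin(vals, [0, 1, 2, 3, 4]).all():
                report.append("items: non-integer or out-of-range values")
        if roster is not None and "subject_id" in items.columns:
            extra = set(items["subject_id"]) - set(roster["subject_id"])
            if extra:
                report.append(f"items: subjects not in roster: "
                              f"{sorted(extra)[:5]}")
    if edges_path is not None:
        edges = read_edges(edges_path)
        if edges.values.shape[1] != n_edges(edges.n_parcels):
            report.append("edges: column count inconsistent with n_parcels")
        if roster is not None:
            extra = set(edges.subject_ids) - set(roster["subject_id"].astype(str))
            if extra:
                report.append(f"edges: subjects not in roster: "
                              f"{sorted(extra)[:5]}")
    return report
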