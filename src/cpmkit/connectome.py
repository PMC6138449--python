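"""Functional-connectivity matrices and their edge-vector representations.

An FC matrix is the parcel × parcel Pearson correlation of a run's
(denoised) parcel time series, Fisher z-transformed (arctanh).  Run
matrices are averaged in z-space into session matrices (REST1, REST2) and
a grand average (REST12).  Because FC matrices are symmetric, the
upper-triangular part (row-major, i<j) is vectorized into an edge vector
of length n(n−1)/2, and subjects' edge vectors are stacked into the
subjects × edges matrix that all prediction and reliability analyses
consume.  Edge values stay on the Fisher-z scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .runs import RunTimeSeries

__all__ = [
    "FCMatrix",
    "EdgeMatrix",
    "fc_matrix",
    "average_fc",
    "n_edges",
    "vectorize_upper",
    "unvectorize_upper",
    "stack_subjects",
]

_Z_CAP = 1.0 - 1e-7  # guard before arctanh for (near-)perfect correlations


@dataclass
class FCMatrix:
    subject_id: str
    session_label: str
    values: np.ndarray  # n_parcels x n_parcels, Fisher-z scale

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC values must be square")
        self.values = v

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeMatrix:
    """Subjects × edges matrix with roster-ordered rows."""

    values: np.ndarray
    subject_ids: list[str]
    session_label: str
    n_parcels: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids),
                                 n_edges(self.n_parcels)):
            raise ValueError("edge matrix shape inconsistent with roster "
                             "and parcel count")


def n_edges(n_parcels: int) -> int:
    """Number of unique parcel pairs: n(n−1)/2."""
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    return n_parcels * (n_parcels - 1) // 2


def fc_matrix(run: RunTimeSeries, session_label: str | None = None) -> FCMatrix:
    """Pearson-correlate parcel channels over retained time points.

    Only time points with ``censor_mask=True`` enter the correlation.  The
    result is Fisher z-transformed with correlations capped at 1−1e−7 in
    magnitude, and the diagonal is set to 0.
    """
    p = run.parcels()[run.censor_mask]
    if p.shape[1] < 2:
        raise ValueError("need at least 2 parcel channels")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 retained time points")
    sd = p.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"parcel {bad} has zero variance over retained "
                         "time points")
    r = np.corrcoef(p, rowvar=False)
    r = np.clip(r, -_Z_CAP, _Z_CAP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCMatrix(subject_id=run.subject_id,
                    session_label=session_label or run.run_label, values=z)


def average_fc(matrices: list[FCMatrix], session_label: str) -> FCMatrix:
    """Element-wise mean of FC matrices in Fisher-z space."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n_parcels != first.n_parcels:
            raise ValueError("parcel-count mismatch in average_fc")
        if m.subject_id != first.subject_id:
            raise ValueError("subject mismatch in average_fc")
    stacked = np.stack([m.values for m in matrices])
    return FCMatrix(subject_id=first.subject_id, session_label=session_label,
                    values=stacked.mean(axis=0))


def vectorize_upper(m: FCMatrix | np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Row-major upper-triangle (i<j) edge vector of a symmetric matrix."""
    v = m.values if isinstance(m, FCMatrix) else np.asarray(m, dtype=float)
    if not np.allclose(v, v.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def unvectorize_upper(edges: np.ndarray, n_parcels: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (diagonal zero)."""
    edges = np.asarray(edges, dtype=float)
    if edges.size != n_edges(n_parcels):
        raise ValueError("edge vector length inconsistent with parcel count")
    out = np.zeros((n_parcels, n_parcels))
    iu = np.triu_indices(n_parcels, k=1)
    out[iu] = edges
    return out + out.T


def stack_subjects(matrices: list[FCMatrix], subject_ids: list[str],
                   session_label: str) -> EdgeMatrix:
    """Stack subjects' edge vectors in the given roster order."""
    by_id = {m.subject_id: m for m in matrices}
    missing = [s for s in subject_ids if s not in by_id]
    if missing:
        raise ValueError(f"missing FC matrices for subjects: {missing[:5]}")
    rows = [vectorize_upper(by_id[s]) for s in subject_ids]
    return EdgeMatrix(values=np.vstack(rows), subject_ids=list(subject_ids),
                      session_label=session_label,
                      n_parcels=matrices[0].n_parcels)
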