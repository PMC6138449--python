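"""Test–retest reliability of connectomes across two sessions.

Three complementary metrics:

* **Identification success rate (ISR)** — connectome fingerprinting:
  subject S is identified if, among all subjects' session-2 edge vectors,
  S's own is the one most correlated with S's session-1 vector.
* **Pairwise-similarity reproducibility** — the subject × subject
  similarity (Pearson) matrix is built within each session and the two
  matrices' upper triangles are correlated.
* **Behavioral-utility reproducibility** — per session, each edge is
  correlated with a stable trait across subjects; the two edgewise
  correlation maps are then correlated across edges.  This captures how
  reliably the connectome's relationship to behavior replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import EdgeMatrix

__all__ = [
    "FingerprintResult",
    "identification_success_rate",
    "similarity_testretest",
    "behavioral_utility_testretest",
]


@dataclass
class FingerprintResult:
    direction: str
    success: np.ndarray        # per-subject booleans
    match_index: np.ndarray    # index of best-matching target subject
    isr: float                 # percentage in [0, 100]


def _check_pair(s1: EdgeMatrix, s2: EdgeMatrix, min_n: int) -> None:
    if s1.subject_ids != s2.subject_ids:
        raise ValueError("sessions cover different subject sets/orders")
    if s1.values.shape != s2.values.shape:
        raise ValueError("edge matrices have different shapes")
    if len(s1.subject_ids) < min_n:
        raise ValueError(f"need at least {min_n} subjects")


def _rows_standardized(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    return xc / norm


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between two edge matrices."""
    return _rows_standardized(a) @ _rows_standardized(b).T


def identification_success_rate(s1: EdgeMatrix, s2: EdgeMatrix,
                                direction: str = "1to2") -> FingerprintResult:
    """Fingerprint each session-1 connectome against all session-2 ones.

    Ties in the correlation argmax are broken to the lowest roster index
    with a warning (exact ties are astronomically unlikely on real data).
    """
    _check_pair(s1, s2, min_n=2)
    if direction == "1to2":
        c = _cross_corr(s1.values, s2.values)
    elif direction == "2to1":
        c = _cross_corr(s2.values, s1.values)
    else:
        raise ValueError("direction must be '1to2' or '2to1'")
    best = np.argmax(c, axis=1)
    ties = (c == c[np.arange(c.shape[0]), best][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} tie(s) in fingerprint matching; "
                      "broken to lowest roster index", stacklevel=2)
    success = best == np.arange(c.shape[0])
    return FingerprintResult(direction=direction, success=success,
                             match_index=best,
                             isr=100.0 * float(success.mean()))


def similarity_testretest(s1: EdgeMatrix, s2: EdgeMatrix) -> float:
    """Correlation of within-session subject-similarity structure.

    The diagonal (self-similarity, identically 1) is excluded; only the
    upper triangles of the two N×N similarity matrices are compared.
    """
    _check_pair(s1, s2, min_n=3)
    sim1 = _cross_corr(s1.values, s1.values)
    sim2 = _cross_corr(s2.values, s2.values)
    iu = np.triu_indices(sim1.shape[0], k=1)
    return float(np.corrcoef(sim1[iu], sim2[iu])[0, 1])


def behavioral_utility_testretest(s1: EdgeMatrix, s2: EdgeMatrix,
                                  score: np.ndarray) -> float:
    """Session-to-session correlation of edgewise trait-correlation maps."""
    _check_pair(s1, s2, min_n=3)
    y = np.asarray(score, dtype=float)
    if y.shape != (len(s1.subject_ids),):
        raise ValueError("score length must match the roster")
    if y.std() == 0:
        raise ValueError("score is constant; behavioral utility undefined")
    map1 = _edgewise_corr(s1.values, y)
    map2 = _edgewise_corr(s2.values, y)
    return float(np.corrcoef(map1, map2)[0, 1])


def _edgewise_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    den = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.nan_to_num(r, nan=0.0)
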