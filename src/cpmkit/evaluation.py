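"""Cross-validated prediction metrics and permutation inference.

In a cross-validation setting the Pearson correlation between observed and
predicted scores must not be squared to obtain a coefficient of
determination.  The proper cross-validated R² compares the model's squared
residuals against the null model that predicts the mean observed score::

    R² = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²

and may be negative when the model does worse than the mean.  The root
mean square deviation (RMSD) is the spread of the residuals, and nRMSD is
RMSD expressed as a fraction of the spread of the observed scores, so that
nRMSD = √(1 − R²) under a matched-denominator ("population") convention.

Because cross-validation folds are not independent, significance is
assessed with a permutation test that shuffles scores between subjects
while keeping the family structure, the confounds, and every other part of
the pipeline fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvaluationResult",
    "NullDistribution",
    "evaluate",
    "nrmsd_from_r2",
    "permutation_test",
]


@dataclass(frozen=True)
class EvaluationResult:
    """Prediction-quality summary for one observed/predicted score pair."""

    r: float
    r2: float
    rmsd: float
    nrmsd: float
    n: int
    constant_pred: bool = False

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "r2": self.r2,
            "rmsd": self.rmsd,
            "nrmsd": self.nrmsd,
            "n": self.n,
            "constant_pred": self.constant_pred,
        }


def evaluate(obs, pred) -> EvaluationResult:
    """Compute r, cross-validated R², RMSD and nRMSD for pooled predictions.

    Uses the population (1/n) convention for both RMSD and the SD of the
    observed scores, so the identity ``nrmsd**2 + r2 == 1`` holds exactly.
    A constant prediction vector has an undefined correlation; it is
    reported as ``r=0`` with ``constant_pred=True`` while R²/RMSD/nRMSD are
    still computed.
    """
    y = np.asarray(obs, dtype=float)
    yhat = np.asarray(pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("obs and pred must be 1-D arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("observed scores are constant; metrics undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmsd = math.sqrt(ss_res / n)
    nrmsd = rmsd / math.sqrt(ss_tot / n)
    constant = bool(np.ptp(yhat) == 0.0)
    if constant:
        r = 0.0
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    return EvaluationResult(r=r, r2=r2, rmsd=rmsd, nrmsd=nrmsd, n=n,
                            constant_pred=constant)


def nrmsd_from_r2(r2: float, n_obs: int | None = None) -> float:
    """Normalized RMSD implied by a cross-validated R².

    With ``n_obs=None`` (default) the population convention is used and the
    conversion is exactly ``sqrt(1 - r2)``.  With a finite ``n_obs`` the
    conversion applies the finite-sample correction ``sqrt((1 - r2) *
    (n - 1) / (n - 2))``, i.e. residuals scaled by the residual degrees of
    freedom of a fitted line (n − 2) against the sample SD (n − 1) of the
    observed scores — the convention of the observed-vs-predicted
    evaluation literature this module follows.
    """
    if r2 > 1:
        raise ValueError(f"R² cannot exceed 1, got {r2}")
    if n_obs is None:
        return math.sqrt(1.0 - r2)
    if n_obs < 3:
        raise ValueError("n_obs must be at least 3")
    return math.sqrt((1.0 - r2) * (n_obs - 1) / (n_obs - 2))


@dataclass
class NullDistribution:
    """Permutation replicates of a prediction metric with an empirical p.

    ``p_empirical`` uses the (k+1)/(n+1) rule, which yields valid p-values
    under exchangeability of the permuted scores.
    """

    observed: float
    replicates: np.ndarray
    n_perm: int
    seed: int
    metric: str = "r"
    n_failed: int = 0
    p_empirical: float = field(init=False)

    def __post_init__(self):
        reps = np.asarray(self.replicates, dtype=float)
        self.replicates = reps
        k = int(np.sum(reps >= self.observed))
        self.p_empirical = (k + 1) / (reps.size + 1)

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "metric": self.metric,
            "n_perm": self.n_perm,
            "n_failed": self.n_failed,
            "p_empirical": self.p_empirical,
            "replicates": self.replicates.tolist(),
            "seed": self.seed,
        }


def permutation_test(run_fn, y, n_perm: int = 1000, seed: int = 0,
                     metric: str = "r") -> NullDistribution:
    """Family-preserving permutation test of a cross-validated metric.

    ``run_fn(scores)`` must rerun the full prediction chain (deconfounding,
    edge filtering, model fitting, cross-validated prediction, evaluation)
    for an arbitrary raw score vector and return an
    :class:`EvaluationResult`.  Each replicate shuffles the raw scores
    uniformly between subjects while everything else — confounds, edges,
    family-based folds — stays exactly as in the observed analysis.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = getattr(run_fn(y), metric)
    reps = []
    n_failed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.size)
        try:
            reps.append(getattr(run_fn(y[perm]), metric))
        except Exception:  # noqa: BLE001 - a failed replicate is recorded
            n_failed += 1
    return NullDistribution(observed=float(observed),
                            replicates=np.asarray(reps), n_perm=n_perm,
                            seed=seed, metric=metric, n_failed=n_failed)
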