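"""NEO Five-Factor Inventory scoring and higher-order personality components.

The NEO-FFI is a 60-item self-report questionnaire answered on a 5-point
Likert scale, coded 0 (strongly disagree) … 4 (strongly agree).  Each Big
Five factor — Openness (O), Conscientiousness (C), Extraversion (E),
Agreeableness (A), Neuroticism (N) — is the sum of 12 items, some of which
are reverse-coded (x ↦ 4 − x), so factor scores range 0–48.  Note that
item 59 belongs to Agreeableness and IS reverse-coded (a coding error for
this item has circulated in at least one public database).

Because the five factors are intercorrelated in typical samples, two
orthogonal superordinate components — conventionally labeled α (stability;
loads mostly on Neuroticism, reversed) and β (plasticity; loads mostly on
Openness/Extraversion) — are extracted with a PCA of the standardized
factor scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "ITEM_CODING",
    "score_neoffi",
    "cronbach_alpha",
    "superordinate_pca",
    "SuperordinatePCA",
    "coded_items",
]

FACTORS = ("O", "C", "E", "A", "N")

# item -> factor map; negative item numbers are reverse-coded (4 - x)
ITEM_CODING: dict[str, tuple[int, ...]] = {
    "O": (-3, -8, 13, -18, -23, 28, -33, -38, 43, -48, 53, 58),
    "C": (5, 10, -15, 20, 25, -30, 35, 40, -45, 50, -55, 60),
    "E": (2, 7, -12, 17, 22, -27, 32, 37, -42, 47, 52, -57),
    "A": (4, -9, -14, 19, -24, -29, 34, -39, -44, 49, -54, -59),
    "N": (-1, 6, 11, -16, 21, 26, -31, 36, 41, -46, 51, 56),
}

_ITEM_COLS = [f"item_{i}" for i in range(1, 61)]


def _item_matrix(items: pd.DataFrame) -> np.ndarray:
    missing = [c for c in _ITEM_COLS if c not in items.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing[:3]}...")
    x = items[_ITEM_COLS].to_numpy()
    bad = np.argwhere(~np.isin(x, [0, 1, 2, 3, 4]))
    if bad.size:
        s, j = bad[0]
        subj = items.index[s] if items.index.name else s
        raise ValueError(
            f"invalid item value at subject {subj}, item {j + 1}: {x[s, j]!r}"
        )
    return x.astype(np.int64)


def coded_items(items: pd.DataFrame, factor: str) -> np.ndarray:
    """Return the reverse-corrected 12-item block for one factor."""
    x = _item_matrix(items)
    cols = []
    for item in ITEM_CODING[factor]:
        v = x[:, abs(item) - 1]
        cols.append(4 - v if item < 0 else v)
    return np.column_stack(cols)


def score_neoffi(items: pd.DataFrame) -> pd.DataFrame:
    """Score 60 NEO-FFI item responses into the five factor sums.

    `items` must carry columns ``item_1`` … ``item_60`` with integer values
    in {0..4}; the subject identifier is taken from the index (or a
    ``subject_id`` column, which is preserved).
    """
    out = pd.DataFrame(index=items.index)
    if "subject_id" in items.columns:
        out["subject_id"] = items["subject_id"]
    for factor in FACTORS:
        out[factor] = coded_items(items, factor).sum(axis=1)
    return out


def cronbach_alpha(items: pd.DataFrame, factor: str) -> float:
    """Internal consistency of one factor's 12 coded items.

    α = k/(k−1) · (1 − Σ var(item_j) / var(Σ item_j)), with unbiased
    (n−1) sample variances computed over subjects.
    """
    block = coded_items(items, factor).astype(float)
    if block.shape[0] < 2:
        raise ValueError("cronbach_alpha needs at least 2 subjects")
    k = block.shape[1]
    total_var = block.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError(f"total score for factor {factor} has zero variance")
    item_var = block.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def normality_report(traits: pd.DataFrame) -> pd.DataFrame:
    """Descriptive D'Agostino-Pearson normality test per factor (optional
    reporting extra; no decision in the pipeline depends on it)."""
    from scipy import stats

    rows = []
    for f in FACTORS:
        stat, p = stats.normaltest(traits[f].to_numpy(dtype=float))
        rows.append({"factor": f, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SuperordinatePCA:
    """First two principal components of the standardized factor scores."""

    scores: pd.DataFrame            # columns: alpha, beta
    loadings: pd.DataFrame          # 5 factors x (alpha, beta)
    variance_explained: np.ndarray  # fractions of total variance, len 2


def superordinate_pca(traits: pd.DataFrame) -> SuperordinatePCA:
    """Extract the α and β superordinate components from factor scores.

    The five factor scores are standardized (zero mean, unit variance)
    before eigendecomposition — a correlation-matrix PCA — and the first
    two components are retained.  Each component's sign is fixed so that
    the factor with the largest absolute loading loads positively.
    """
    z = traits.loc[:, list(FACTORS)].to_numpy(dtype=float)
    if z.shape[0] < 5:
        raise ValueError("superordinate_pca needs at least 5 subjects")
    sd = z.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        flat = [f for f, s in zip(FACTORS, sd) if s <= 0]
        raise ValueError(f"zero-variance factor(s): {flat}")
    z = (z - z.mean(axis=0)) / sd
    corr = (z.T @ z) / (z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-10:
        raise ValueError("factor correlation matrix is rank deficient")
    comp = evecs[:, :2]
    for j in range(2):
        if comp[np.argmax(np.abs(comp[:, j])), j] < 0:
            comp[:, j] = -comp[:, j]
    pcs = z @ comp
    # unit-variance component scores
    pcs = pcs / pcs.std(axis=0, ddof=1)
    scores = pd.DataFrame(pcs, columns=["alpha", "beta"], index=traits.index)
    if "subject_id" in traits.columns:
        scores.insert(0, "subject_id", traits["subject_id"])
    loadings = pd.DataFrame(comp * np.sqrt(evals[:2]),
                            index=list(FACTORS), columns=["alpha", "beta"])
    return SuperordinatePCA(scores=scores, loadings=loadings,
                            variance_explained=evals[:2] / len(FACTORS))
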