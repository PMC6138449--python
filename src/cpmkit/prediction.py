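"""Family-aware cross-validated prediction of traits from connectomes.

The prediction chain, run independently inside every cross-validation
fold so that no information flows from test to train:

1. **Deconfounding** — ordinary least squares of the trait on the
   confounds, fitted on training subjects only; the fitted weights are
   applied to both training and test scores, yielding residualized traits.
2. **Edge filtering** — each edge is Pearson-correlated with the training
   scores; edges with two-sided p < .01 (via the exact t-transform
   t = r·√((n−2)/(1−r²))) are kept, split into positively and negatively
   correlated sets.
3. **Model fit** — either the univariate network-strength model (sum of
   selected edge weights regressed on the score; separate positive and
   negative models) or a multivariate elastic net on the union of selected
   edges, with L1 ratio 0.01 (nearly ridge) and the penalty weight α
   chosen by an inner 3-fold cross-validation stratified by quartiles of
   the training scores.

Folds are leave-one-family-out (LOFO): each test set is one entire
family, so genetically related subjects never straddle the train/test
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import StratifiedKFold

from .connectome import EdgeMatrix

__all__ = [
    "DeconfoundModel",
    "ModelConfig",
    "PredictionResult",
    "fit_deconfound",
    "apply_deconfound",
    "lofo_splits",
    "filter_edges",
    "cpm_univariate",
    "elasticnet_model",
    "predict_cv",
    "cv_runner",
]

MODELS = ("univariate_pos", "univariate_neg", "elastic_net")


@dataclass(frozen=True)
class ModelConfig:
    model: str = "univariate_pos"
    filter_p: float = 0.01
    l1_ratio: float = 0.01
    n_alphas: int = 50
    inner_folds: int = 3
    deconfound_set: str = "full"

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.filter_p < 1:
            raise ValueError("filter_p must be in (0, 1)")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in [0, 1]")


@dataclass
class DeconfoundModel:
    confound_names: list[str]
    coefficients: np.ndarray      # [intercept, one per confound]
    fitted_on: np.ndarray         # training subject indices


def fit_deconfound(y: np.ndarray, confounds: np.ndarray,
                   train_idx: np.ndarray,
                   confound_names: list[str] | None = None) -> DeconfoundModel:
    """OLS of the trait on the confounds over training subjects only."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if np.isnan(c).any() or np.isnan(y).any():
        raise ValueError("missing values in scores or confounds")
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size < c.shape[1] + 2:
        raise ValueError("too few training subjects for the confound model")
    d = np.column_stack([np.ones(train_idx.size), c[train_idx]])
    coef, _, rank, _ = np.linalg.lstsq(d, y[train_idx], rcond=None)
    if rank < d.shape[1]:
        warnings.warn("collinear confounds; coefficients are a minimum-norm "
                      "solution", stacklevel=2)
    names = confound_names or [f"c{i}" for i in range(c.shape[1])]
    return DeconfoundModel(confound_names=list(names), coefficients=coef,
                           fitted_on=train_idx)


def apply_deconfound(model: DeconfoundModel, y: np.ndarray,
                     confounds: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Residualize scores of `idx` subjects using the stored coefficients."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(confounds, dtype=float)
    idx = np.asarray(idx, dtype=int)
    d = np.column_stack([np.ones(idx.size), c[idx]])
    return y[idx] - d @ model.coefficients


def lofo_splits(family_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-family-out folds: one per unique family id, ordered by id.

    Test folds partition the cohort; all-singleton families reduce to
    leave-one-out.
    """
    fam = np.asarray(family_ids)
    if fam.dtype.kind == "f" and np.isnan(fam.astype(float)).any():
        raise ValueError("missing family id")
    if any(f is None or (isinstance(f, str) and not f) for f in fam.tolist()):
        raise ValueError("missing family id")
    all_idx = np.arange(fam.size)
    splits = []
    for f in sorted(set(fam.tolist())):
        test = all_idx[fam == f]
        train = all_idx[fam != f]
        splits.append((train, test))
    return splits


@lru_cache(maxsize=4096)
def _r_threshold(n: int, p: float) -> float:
    """|r| above which the two-sided p-value of r's t-transform is < p."""
    t_crit = stats.t.isf(p / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit ** 2))


def edge_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of `x` with `y` (0 for constant columns)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    den = np.linalg.norm(xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / den
    return np.nan_to_num(r, nan=0.0)


def filter_edges(x_train: np.ndarray, y_train: np.ndarray,
                 p_thresh: float = 0.01, return_p: bool = False):
    """Select edges whose correlation with the score has two-sided p < p_thresh.

    Returns ``(pos_mask, neg_mask)`` — sign-disjoint boolean edge masks —
    or ``(pos_mask, neg_mask, p_values)`` when `return_p` is set.
    Zero-variance edges are never selected.
    """
    y_train = np.asarray(y_train, dtype=float)
    n = y_train.size
    if n <= 3:
        raise ValueError("need more than 3 training subjects")
    if y_train.std() == 0:
        raise ValueError("constant training score")
    r = edge_correlations(np.asarray(x_train, dtype=float), y_train)
    r_crit = _r_threshold(n, p_thresh)
    sig = np.abs(r) > r_crit
    pos_mask = sig & (r > 0)
    neg_mask = sig & (r < 0)
    if not return_p:
        return pos_mask, neg_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pos_mask, neg_mask, p


def cpm_univariate(x_train: np.ndarray, y_train: np.ndarray,
                   x_test: np.ndarray, mask: np.ndarray
                   ) -> tuple[np.ndarray, dict]:
    """Network-strength model: regress the score on the sum of selected
    edge weights; predict test subjects from their strengths.

    An empty mask, or zero strength variance on the training fold, falls
    back to predicting the training mean (recorded in the fit info).
    """
    info = {"n_selected": int(mask.sum()), "fallback": False}
    if mask.sum() == 0:
        info["fallback"] = True
        return np.full(x_test.shape[0], y_train.mean()), info
    s_train = x_train[:, mask].sum(axis=1)
    s_test = x_test[:, mask].sum(axis=1)
    if s_train.std() == 0:
        info["fallback"] = True
        return np.full(x_test.shape[0], y_train.mean()), info
    slope, intercept = np.polyfit(s_train, y_train, 1)
    info["slope"], info["intercept"] = float(slope), float(intercept)
    return intercept + slope * s_test, info


def _alpha_grid(x: np.ndarray, y: np.ndarray, l1_ratio: float,
                n_alphas: int) -> np.ndarray:
    """Geometric grid of penalty weights spanning [1e−4, 1]·α_max, where
    α_max is the smallest penalty that zeroes every coefficient."""
    n = x.shape[0]
    alpha_max = np.max(np.abs(x.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * 1e-4, n_alphas)  # decreasing


def _quartile_bins(y: np.ndarray) -> np.ndarray:
    """Four equal-count strata of y (by rank; ties broken by position)."""
    order = np.argsort(y, kind="stable")
    bins = np.empty(y.size, dtype=int)
    bins[order] = (np.arange(y.size) * 4) // y.size
    return bins


def elasticnet_model(x_train: np.ndarray, y_train: np.ndarray,
                     x_test: np.ndarray, mask_union: np.ndarray,
                     config: ModelConfig, seed: int = 0
                     ) -> tuple[np.ndarray, dict]:
    """Elastic net on the union of filtered edges with nested α selection.

    Features are standardized by training mean/SD.  α is picked from a
    50-point geometric grid by 3-fold inner cross-validation stratified on
    quartile bins of the training scores, minimizing mean inner-fold
    squared error (ties go to the larger, more regularized α); the final
    model is refit on the whole training fold.
    """
    info = {"n_selected": int(mask_union.sum()), "fallback": False}
    if mask_union.sum() == 0:
        info["fallback"] = True
        return np.full(x_test.shape[0], y_train.mean()), info
    xt = x_train[:, mask_union]
    mu, sd = xt.mean(axis=0), xt.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xt = np.asfortranarray((xt - mu) / sd)
    xs = (x_test[:, mask_union] - mu) / sd
    y_train = np.ascontiguousarray(y_train, dtype=float)
    alphas = _alpha_grid(xt, y_train, config.l1_ratio, config.n_alphas)

    bins = _quartile_bins(y_train)
    n_splits = config.inner_folds
    min_class = np.bincount(bins, minlength=4).min()
    if min_class < n_splits:
        n_splits = max(2, int(min_class))
        warnings.warn(f"inner folds reduced to {n_splits} (small training "
                      "fold)", stacklevel=2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    sse = np.zeros(alphas.size)
    with warnings.catch_warnings():
        # the smallest path alphas need not fully converge for selection
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, va in skf.split(xt, bins):
            ym = y_train[tr].mean()
            _, coefs, _ = enet_path(np.asfortranarray(xt[tr]),
                                    np.ascontiguousarray(y_train[tr] - ym),
                                    l1_ratio=config.l1_ratio, alphas=alphas,
                                    check_input=False)
            pred = xt[va] @ coefs + ym  # n_val x n_alphas
            sse += ((pred - y_train[va][:, None]) ** 2).sum(axis=0)
        # alphas decreasing: first index of the min is the largest alpha
        best = int(np.argmin(sse))
        alpha = float(alphas[best])
        final = ElasticNet(alpha=alpha, l1_ratio=config.l1_ratio,
                           max_iter=20000, tol=1e-10)
        final.fit(xt, y_train, check_input=False)
    info.update(alpha=alpha, alpha_grid=(float(alphas[0]), float(alphas[-1])),
                n_nonzero=int(np.sum(final.coef_ != 0)),
                standardize_mu=mu, standardize_sd=sd, coef=final.coef_.copy())
    return final.predict(xs), info


@dataclass
class PredictionResult:
    """Pooled cross-validated predictions with per-fold bookkeeping."""

    observed: np.ndarray          # fold-specific deconfounded test scores
    predicted: np.ndarray
    fold_id: np.ndarray           # per subject, index of its (test) fold
    config: ModelConfig
    fold_info: list[dict] = field(default_factory=list)

    def metrics(self):
        from .evaluation import evaluate

        return evaluate(self.observed, self.predicted)


def predict_cv(x, y, confounds, family_ids, config: ModelConfig,
               seed: int = 0, record_artifacts: bool = True
               ) -> PredictionResult:
    """Leave-one-family-out cross-validated prediction.

    For each fold: fit the deconfound model on training subjects →
    residualize train and test scores → filter edges on the training fold
    → fit the configured model → predict the held-out family.  The
    recorded observed scores are the fold-specific deconfounded test
    values, so pooled metrics compare like with like.
    """
    xv = x.values if isinstance(x, EdgeMatrix) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if xv.shape[0] != n or len(np.asarray(family_ids)) != n:
        raise ValueError("inconsistent subject counts across inputs")
    use_conf = confounds is not None and np.size(confounds) > 0
    if use_conf:
        conf = np.asarray(confounds, dtype=float)
        if conf.shape[0] != n:
            raise ValueError("inconsistent subject counts across inputs")

    observed = np.empty(n)
    predicted = np.empty(n)
    fold_id = np.empty(n, dtype=int)
    fold_info: list[dict] = []

    xv = np.ascontiguousarray(xv)
    # column totals over all subjects; train-fold sums are obtained by
    # subtracting the (small) test family's contribution
    col_sum = xv.sum(axis=0)
    col_sq = np.einsum("ij,ij->j", xv, xv)
    univariate = config.model in ("univariate_pos", "univariate_neg")

    for k, (train, test) in enumerate(lofo_splits(family_ids)):
        if use_conf:
            dc = fit_deconfound(y, conf, train)
            y_tr = apply_deconfound(dc, y, conf, train)
            y_te = apply_deconfound(dc, y, conf, test)
        else:
            dc = None
            mu = y[train].mean()
            y_tr, y_te = y[train] - mu, y[test] - mu
        if y_tr.std() == 0:
            raise ValueError("constant training score")
        n_tr = train.size
        x_te = xv[test]
        s1 = col_sum - x_te.sum(axis=0)
        s2 = col_sq - np.einsum("ij,ij->j", x_te, x_te)
        y_full = np.zeros(n)
        y_full[train] = y_tr
        sxy = xv.T @ y_full
        mx = s1 / n_tr
        vy = float(y_tr @ y_tr) - n_tr * y_tr.mean() ** 2
        varx = s2 - n_tr * mx ** 2
        den = np.sqrt(np.clip(varx, 0, None) * vy)
        cov = sxy - mx * y_tr.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, cov / np.maximum(den, 1e-300), 0.0)
        r_crit = _r_threshold(n_tr, config.filter_p)
        sig = np.abs(r) > r_crit
        pos = sig & (r > 0)
        neg = sig & (r < 0)
        if univariate:
            mask = pos if config.model == "univariate_pos" else neg
            info = {"n_selected": int(mask.sum()), "fallback": False}
            if mask.any():
                xm = xv[:, mask]
                s_tr, s_te = xm[train].sum(axis=1), xm[test].sum(axis=1)
                vs = s_tr.var()
                if vs > 0:
                    slope = np.cov(s_tr, y_tr, bias=True)[0, 1] / vs
                    intercept = y_tr.mean() - slope * s_tr.mean()
                    pred = intercept + slope * s_te
                    info["slope"], info["intercept"] = float(slope), float(intercept)
                else:
                    info["fallback"] = True
                    pred = np.full(test.size, y_tr.mean())
            else:
                info["fallback"] = True
                pred = np.full(test.size, y_tr.mean())
        else:
            pred, info = elasticnet_model(xv[train], y_tr, x_te,
                                          pos | neg, config, seed=seed + k)
        observed[test] = y_te
        predicted[test] = pred
        fold_id[test] = k
        if record_artifacts:
            info = dict(info)
            info["fold"] = k
            info["n_pos"], info["n_neg"] = int(pos.sum()), int(neg.sum())
            info["pos_mask"], info["neg_mask"] = pos.copy(), neg.copy()
            if dc is not None:
                info["deconfound_coef"] = dc.coefficients.copy()
            fold_info.append(info)

    return PredictionResult(observed=observed, predicted=predicted,
                            fold_id=fold_id, config=config,
                            fold_info=fold_info)


def cv_runner(x, confounds, family_ids, config: ModelConfig, seed: int = 0):
    """Build a ``scores -> EvaluationResult`` callable over a fixed design.

    This is the unit the permutation test reruns: everything except the
    raw score vector (edges, confounds, family folds, configuration) is
    frozen in the closure.
    """
    def run(y):
        res = predict_cv(x, y, confounds, family_ids, config, seed=seed,
                         record_artifacts=False)
        return res.metrics()

    return run
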