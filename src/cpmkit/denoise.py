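"""Three alternative resting-state denoising pipelines (A, B, C).

Resting-state fMRI signals carry drift, motion, and physiological noise;
no single cleanup strategy is consensual, so three common alternatives are
implemented as ordered compositions of labeled operators:

* **Pipeline A** (fingerprinting-style, 7 steps): z-score each channel →
  third-degree Legendre detrend of CSF/WM → regress mean CSF and WM
  signals from parcels → motion regression (6 realignment parameters and
  their derivatives) → Gaussian low-pass (SD = 1 TR) → third-degree
  Legendre detrend of parcels → global-signal regression.
* **Pipeline B** (36-parameter-style, 4 steps): demean → linear+quadratic
  detrend → first-order Butterworth band-pass 0.01–0.08 Hz (censored
  volumes linearly interpolated first) → one combined regression {CSF, WM,
  their derivatives and squares; 24 motion expansions; global signal with
  derivative and square; one spike regressor per censored volume}.
* **Pipeline C** (CompCor-style; assumes ICA-FIX-like input, i.e. no
  structured artifacts): demean → linear detrend → regress {5 CompCor
  components from WM/CSF, mean parcel signal, whole-brain signal} fitted on
  uncensored volumes (FD > 0.25 mm or DVARS > 105% of run median) →
  band-pass with interpolation over censored volumes.  Censored volumes
  remain flagged and are excluded from FC computation downstream.

Censoring is always a mask, never a deletion: every pipeline preserves the
number of parcel channels and time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import ndimage, signal

from .runs import SIGNAL_ROLES, RunTimeSeries

__all__ = [
    "DenoiseConfig",
    "zscore_channels",
    "legendre_detrend",
    "regress_nuisance",
    "expand_motion",
    "gaussian_lowpass",
    "butter_bandpass",
    "censor_volumes",
    "compcor",
    "denoise",
]


@dataclass(frozen=True)
class DenoiseConfig:
    pipeline: str = "A"
    legendre_degree: int = 3
    gaussian_sd_s: float = 0.72
    butter_order: int = 1
    passband_hz: tuple[float, float] = (0.01, 0.08)
    fd_censor_mm: float = 0.25
    dvars_censor_ratio: float = 1.05
    compcor_k: int = 5

    def __post_init__(self):
        if self.pipeline not in ("A", "B", "C"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        low, high = self.passband_hz
        if not (0 < low < high):
            raise ValueError("passband must satisfy 0 < low < high")
        if self.legendre_degree < 0:
            raise ValueError("legendre_degree must be >= 0")


def _require_roles(run: RunTimeSeries, roles: tuple[str, ...]) -> None:
    present = set(run.channel_roles)
    for role in roles:
        if role not in present:
            raise ValueError(f"pipeline requires channel role {role!r}")


def zscore_channels(run: RunTimeSeries,
                    roles: tuple[str, ...] = SIGNAL_ROLES) -> RunTimeSeries:
    """Normalize each targeted channel to mean 0, sample SD 1.

    Zero-variance channels cannot be normalized; they are zeroed out (and
    thereby dropped from any later correlation) with a warning.
    """
    x = run.channels.copy()
    idx = run.role_idx(*roles)
    sub = x[:, idx]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance channel(s) dropped "
                      "during z-scoring", stacklevel=2)
        sd = np.where(flat, 1.0, sd)
    out = (sub - mu) / sd
    out[:, flat] = 0.0
    x[:, idx] = out
    return run.with_channels(x, step="zscore")


def _legendre_basis(t: int, degree: int) -> np.ndarray:
    grid = np.linspace(-1.0, 1.0, t)
    return npleg.legvander(grid, degree)  # columns P0..Pdeg


def legendre_detrend(run: RunTimeSeries, degree: int,
                     roles: tuple[str, ...]) -> RunTimeSeries:
    """Remove the least-squares projection onto Legendre polynomials
    P0..P_degree (evaluated on [−1, 1] over the run) from the given roles."""
    t = run.n_timepoints
    if t < degree + 2:
        raise ValueError("too few time points for requested degree")
    basis = _legendre_basis(t, degree)
    x = run.channels.copy()
    idx = run.role_idx(*roles)
    coef, *_ = np.linalg.lstsq(basis, x[:, idx], rcond=None)
    x[:, idx] = x[:, idx] - basis @ coef
    return run.with_channels(x, step=f"legendre_detrend(deg={degree},"
                                     f"roles={'/'.join(roles)})")


def regress_nuisance(run: RunTimeSeries, design: np.ndarray,
                     roles: tuple[str, ...] = ("parcel",),
                     sample_mask: np.ndarray | None = None,
                     step: str = "regress") -> RunTimeSeries:
    """OLS-residualize the targeted channels on a design matrix.

    An intercept is always included.  Collinear design columns are dropped
    with a warning.  If `sample_mask` is given, coefficients are fitted on
    the retained rows only but residuals are formed for all rows.
    """
    t = run.n_timepoints
    design = np.asarray(design, dtype=float)
    if design.size == 0:
        design = np.empty((t, 0))
    if design.shape[0] != t:
        raise ValueError("design row count must match time")
    d = np.column_stack([np.ones(t), design])
    # drop collinear columns via rank-revealing QR on the fit rows
    fit_rows = np.ones(t, dtype=bool) if sample_mask is None else sample_mask
    q, r, piv = _qr_col_select(d[fit_rows])
    if len(piv) < d.shape[1]:
        warnings.warn(f"dropped {d.shape[1] - len(piv)} collinear design "
                      "column(s)", stacklevel=2)
    d = d[:, piv]
    x = run.channels.copy()
    idx = run.role_idx(*roles)
    coef, *_ = np.linalg.lstsq(d[fit_rows], x[fit_rows][:, idx], rcond=None)
    x[:, idx] = x[:, idx] - d @ coef
    return run.with_channels(x, step=step)


def _qr_col_select(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pivoted QR; return the kept (independent) column indices in order."""
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(a.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0)
    rank = int(np.sum(diag > tol)) if diag.size else 0
    keep = sorted(piv[:rank])
    return q, r, keep


def expand_motion(motion_params: np.ndarray, mode: str = "A") -> np.ndarray:
    """Motion-regressor expansion.

    Mode ``A``: 6 realignment parameters + backward-difference derivatives
    (12 columns).  Mode ``B``: parameters, derivatives, squared parameters
    and squared derivatives (24 columns).  Derivatives have a zero first
    row.
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion_params must be time x 6")
    d = np.zeros_like(m)
    d[1:] = np.diff(m, axis=0)
    if mode == "A":
        return np.column_stack([m, d])
    if mode == "B":
        return np.column_stack([m, d, m ** 2, d ** 2])
    raise ValueError(f"unknown motion expansion mode {mode!r}")


def gaussian_lowpass(run: RunTimeSeries, sd_s: float,
                     roles: tuple[str, ...] = ("parcel",)) -> RunTimeSeries:
    """Temporal smoothing with a unit-sum Gaussian kernel of SD `sd_s`
    seconds (truncated at ±4 SD, reflect-padded boundaries)."""
    if sd_s <= 0:
        raise ValueError("sd_s must be positive")
    sigma = sd_s / run.tr_s
    x = run.channels.copy()
    idx = run.role_idx(*roles)
    x[:, idx] = ndimage.gaussian_filter1d(x[:, idx], sigma=sigma, axis=0,
                                          mode="reflect", truncate=4.0)
    return run.with_channels(x, step=f"gaussian_lowpass(sd={sd_s}s)")


def _interpolate_censored(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linear interpolation of censored rows from retained neighbors;
    edges held at the nearest retained value."""
    if mask.all():
        return x
    if not mask.any():
        raise ValueError("all volumes censored; cannot interpolate")
    t = np.arange(x.shape[0])
    out = x.copy()
    good = t[mask]
    for j in range(x.shape[1]):
        out[~mask, j] = np.interp(t[~mask], good, x[mask, j])
    return out


def butter_bandpass(run: RunTimeSeries, order: int, low_hz: float,
                    high_hz: float,
                    roles: tuple[str, ...] = SIGNAL_ROLES) -> RunTimeSeries:
    """Zero-phase Butterworth band-pass after interpolating censored rows.

    Censored time points are linearly interpolated from the nearest
    retained neighbors before filtering (so spikes do not ring through the
    filter); the forward-backward pass doubles the effective order but
    leaves phase untouched, which matters for correlation structure.
    """
    nyq = 0.5 / run.tr_s
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("need 0 < low < high < Nyquist")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / run.tr_s, output="sos")
    x = run.channels.copy()
    idx = run.role_idx(*roles)
    filled = _interpolate_censored(x[:, idx], run.censor_mask)
    x[:, idx] = signal.sosfiltfilt(sos, filled, axis=0)
    return run.with_channels(
        x, step=f"butter_bandpass({low_hz}-{high_hz}Hz,order={order})")


def censor_volumes(run: RunTimeSeries, fd_thresh_mm: float = 0.25,
                   dvars_ratio: float | None = None) -> np.ndarray:
    """Censoring mask from FD (and optionally DVARS) criteria.

    A volume is censored when FD exceeds `fd_thresh_mm`, or — if
    `dvars_ratio` is given — when its DVARS exceeds `dvars_ratio` times
    the run-median DVARS.  The first volume is never censored by the
    DVARS (difference-based) criterion.
    """
    mask = run.fd <= fd_thresh_mm
    if dvars_ratio is not None:
        dv = run.dvars()
        med = np.median(dv[1:]) if run.n_timepoints > 1 else 0.0
        bad = dv > dvars_ratio * med
        bad[0] = False
        mask &= ~bad
    return mask


def compcor(run: RunTimeSeries, k: int = 5) -> np.ndarray:
    """Top-k principal component time courses of the pooled WM+CSF channels
    (each channel demeaned and variance-normalized first)."""
    if k == 0:
        return np.empty((run.n_timepoints, 0))
    idx = run.role_idx("WM", "CSF")
    x = run.channels[:, idx]
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] < k:
        raise ValueError(f"CompCor needs >= {k} non-degenerate WM/CSF "
                         f"channels, found {x.shape[1]}")
    if run.n_timepoints <= k:
        raise ValueError("CompCor needs more time points than components")
    x = (x - x.mean(axis=0)) / x[:, :].std(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def _deriv(v: np.ndarray) -> np.ndarray:
    d = np.zeros_like(v)
    d[1:] = np.diff(v, axis=0)
    return d


def _role_mean(run: RunTimeSeries, role: str) -> np.ndarray:
    return run.channels[:, run.role_idx(role)].mean(axis=1, keepdims=True)


def denoise(run: RunTimeSeries, config: DenoiseConfig) -> RunTimeSeries:
    """Apply the configured pipeline in its fixed step order."""
    if config.pipeline == "A":
        return _pipeline_a(run, config)
    if config.pipeline == "B":
        return _pipeline_b(run, config)
    return _pipeline_c(run, config)


def _pipeline_a(run: RunTimeSeries, cfg: DenoiseConfig) -> RunTimeSeries:
    _require_roles(run, ("parcel", "WM", "CSF", "global"))
    r = zscore_channels(run)
    r = legendre_detrend(r, cfg.legendre_degree, roles=("WM", "CSF"))
    tissue = np.column_stack([_role_mean(r, "CSF"), _role_mean(r, "WM")])
    r = regress_nuisance(r, tissue, step="tissue_regression(CSF,WM)")
    r = regress_nuisance(r, expand_motion(r.motion_params, "A"),
                         step="motion_regression(12)")
    r = gaussian_lowpass(r, cfg.gaussian_sd_s)
    r = legendre_detrend(r, cfg.legendre_degree, roles=("parcel",))
    r = regress_nuisance(r, _role_mean(r, "global"), step="gsr")
    return r


def _pipeline_b(run: RunTimeSeries, cfg: DenoiseConfig) -> RunTimeSeries:
    _require_roles(run, ("parcel", "WM", "CSF", "global"))
    x = run.channels.copy()
    idx = run.role_idx(*SIGNAL_ROLES)
    x[:, idx] -= x[:, idx].mean(axis=0)
    r = run.with_channels(x, step="demean")
    r = _poly_detrend(r, degree=2)
    mask = censor_volumes(r, cfg.fd_censor_mm, dvars_ratio=None)
    r.censor_mask = mask
    low, high = cfg.passband_hz
    r = butter_bandpass(r, cfg.butter_order, low, high)
    csf, wm = _role_mean(r, "CSF"), _role_mean(r, "WM")
    gs = _role_mean(r, "global")
    spikes = np.eye(r.n_timepoints)[:, ~mask]
    design = np.column_stack([
        csf, wm, _deriv(csf), _deriv(wm), csf ** 2, wm ** 2,
        expand_motion(r.motion_params, "B"),
        gs, _deriv(gs), gs ** 2,
        spikes,
    ])
    r = regress_nuisance(r, design, step="combined_regression(36p+spikes)")
    # censored volumes were absorbed by spike regressors; all volumes kept
    r.censor_mask = np.ones(r.n_timepoints, dtype=bool)
    return r


def _pipeline_c(run: RunTimeSeries, cfg: DenoiseConfig) -> RunTimeSeries:
    _require_roles(run, ("parcel", "WM", "CSF", "global"))
    x = run.channels.copy()
    idx = run.role_idx(*SIGNAL_ROLES)
    x[:, idx] -= x[:, idx].mean(axis=0)
    r = run.with_channels(x, step="demean")
    r = _poly_detrend(r, degree=1)
    mask = censor_volumes(r, cfg.fd_censor_mm,
                          dvars_ratio=cfg.dvars_censor_ratio)
    r.censor_mask = mask
    design = np.column_stack([
        compcor(r, cfg.compcor_k),
        _role_mean(r, "parcel"),
        _role_mean(r, "global"),
    ])
    r = regress_nuisance(r, design, sample_mask=mask,
                         step="compcor_gm_wb_regression")
    low, high = cfg.passband_hz
    r = butter_bandpass(r, cfg.butter_order, low, high)
    r.censor_mask = mask  # censored volumes are discarded at FC time
    return r


def _poly_detrend(run: RunTimeSeries, degree: int) -> RunTimeSeries:
    """Ordinary polynomial detrend of all signal channels."""
    t = run.n_timepoints
    grid = np.linspace(-1.0, 1.0, t)
    basis = np.vander(grid, degree + 1, increasing=True)
    x = run.channels.copy()
    idx = run.role_idx(*SIGNAL_ROLES)
    coef, *_ = np.linalg.lstsq(basis, x[:, idx], rcond=None)
    x[:, idx] = x[:, idx] - basis @ coef
    return run.with_channels(x, step=f"poly_detrend(deg={degree})")
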