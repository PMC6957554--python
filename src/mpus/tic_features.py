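"""Per-pixel time-intensity-curve (TIC) quantification.

A contrast bolus passing a pixel is modelled by a modified local density
random walk (LDRW) curve

    C(t) = alpha * sqrt(kappa / (2 pi (t - t0)))
                 * exp(-kappa * (t - t0 - mu)**2 / (2 (t - t0)))     for t > t0

with mean transit time ``mu`` (s), dispersion-related parameter ``kappa``
(1/s), area under the curve ``alpha`` (a.u.*s) and arrival offset ``t0`` (s).
The spatial density above integrates to exactly ``alpha`` over
``t in (t0, inf)``, which ties the fitted ``alpha`` to the wash-in/wash-out
area regardless of the other parameters.

Alongside the model fit, heuristic bolus descriptors are extracted from the
smoothed curve: appearance time AT (first 5 %-of-peak crossing), peak time PT,
peak intensity PI, and wash-in time WIT (10 % -> 90 % rise time on the rising
limb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from mpus.data_model import BASE_UNITS, DcePlane, ParamMap, RunConfig

TIC_MAP_NAMES = ("mu", "kappa", "alpha", "AT", "PT", "PI", "WIT")


@dataclass
class Tic:
    """One pixel's time-intensity curve (seconds, linear intensity)."""

    t: np.ndarray
    y: np.ndarray
    pixel: tuple[int, int] = (-1, -1)
    valid: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class LdrwFit:
    mu: float
    kappa: float
    alpha: float
    t0: float
    baseline: float
    rss: float
    converged: bool


@dataclass
class HeuristicParams:
    AT: float
    PT: float
    PI: float
    WIT: float
    valid: bool = True


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def ldrw_model(t: np.ndarray, alpha: float, kappa: float, mu: float,
               t0: float) -> np.ndarray:
    """Closed-form LDRW bolus curve; zero at and before ``t0``."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 1e-12
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        tp = tau[pos]
        out[pos] = alpha * np.sqrt(kappa / (2.0 * np.pi * tp)) * np.exp(
            -kappa * (tp - mu) ** 2 / (2.0 * tp)
        )
    return out


def _ldrw_jacobian(t: np.ndarray, alpha: float, kappa: float, mu: float,
                   t0: float) -> np.ndarray:
    m = ldrw_model(t, alpha, kappa, mu, t0)
    tau = np.asarray(t, dtype=float) - t0
    J = np.zeros((len(t), 4))
    pos = tau > 1e-12
    tp = tau[pos]
    mp = m[pos]
    J[pos, 0] = mp / alpha
    J[pos, 1] = mp * (0.5 / kappa - (tp - mu) ** 2 / (2.0 * tp))
    J[pos, 2] = mp * kappa * (tp - mu) / tp
    J[pos, 3] = mp * (0.5 / tp + 0.5 * kappa * (1.0 - mu ** 2 / tp ** 2))
    return J


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _lowpass_matrix(Y: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass along axis 0."""
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2.0:
        return Y
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, Y, axis=0)


def preprocess_curves(t: np.ndarray, Y: np.ndarray,
                      config: RunConfig | None = None) -> np.ndarray:
    """Baseline-subtract, clip and low-pass a (time, pixel) curve matrix.

    Baseline is the per-pixel median over the first ``baseline_window_s``
    seconds (assumed pre-arrival); negative excursions are clipped at zero
    before zero-phase low-pass filtering at ``lowpass_cutoff_hz``.
    """
    cfg = config or RunConfig()
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    pre = t <= t[0] + cfg.baseline_window_s
    baseline = np.median(Y[pre], axis=0)
    Y = np.clip(Y - baseline, 0.0, None)
    fs = 1.0 / float(np.median(np.diff(t)))
    Y = np.clip(_lowpass_matrix(Y, fs, cfg.lowpass_cutoff_hz), 0.0, None)
    return Y


def preprocess_tic(tic: Tic, config: RunConfig | None = None) -> Tic:
    """Preprocess one TIC; curves shorter than 20 samples or spanning less
    than 60 s are returned unchanged with ``valid=False``."""
    if len(tic.t) < 20 or (tic.t[-1] - tic.t[0]) < 60.0:
        return Tic(tic.t, tic.y, tic.pixel, valid=False)
    y = preprocess_curves(tic.t, tic.y[:, None], config)[:, 0]
    return Tic(tic.t, y, tic.pixel, valid=True)


# ---------------------------------------------------------------------------
# heuristic bolus parameters
# ---------------------------------------------------------------------------


def _crossing_times(t: np.ndarray, Y: np.ndarray, thresholds: np.ndarray,
                    stop_idx: np.ndarray | None = None) -> np.ndarray:
    """Per-column first up-crossing time of ``Y`` through ``thresholds``,
    linearly interpolated between samples; restricted to samples at or before
    ``stop_idx`` when given.  Columns that never cross yield NaN."""
    T, N = Y.shape
    Ym = Y.copy()
    if stop_idx is not None:
        beyond = np.arange(T)[:, None] > stop_idx[None, :]
        Ym[beyond] = -np.inf
    hit = Ym >= thresholds[None, :]
    has = hit.any(axis=0)
    i = np.argmax(hit, axis=0)
    prev = np.maximum(i - 1, 0)
    y1 = Y[i, np.arange(N)]
    y0 = Y[prev, np.arange(N)]
    denom = y1 - y0
    frac = np.where((i > 0) & (denom > 0), (thresholds - y0) / np.where(denom > 0, denom, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    tc = t[prev] + frac * (t[i] - t[prev])
    tc[i == 0] = t[0]
    tc[~has] = np.nan
    return tc


def heuristic_params_matrix(t: np.ndarray, Y: np.ndarray,
                            config: RunConfig | None = None
                            ) -> dict[str, np.ndarray]:
    """Vectorized AT/PT/PI/WIT for a preprocessed (time, pixel) matrix."""
    cfg = config or RunConfig()
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    PI = Y.max(axis=0)
    pt_idx = Y.argmax(axis=0)  # first maximum on ties
    PT = t[pt_idx].astype(float)
    AT = _crossing_times(t, Y, cfg.at_threshold_frac * PI)
    t_lo = _crossing_times(t, Y, cfg.wit_low_frac * PI, stop_idx=pt_idx)
    t_hi = _crossing_times(t, Y, cfg.wit_high_frac * PI, stop_idx=pt_idx)
    WIT = t_hi - t_lo
    invalid = PI <= 0
    for arr in (AT, PT, WIT):
        arr[invalid] = np.nan
    PI = np.where(invalid, np.nan, PI)
    return {"AT": AT, "PT": PT, "PI": PI, "WIT": WIT}


def heuristic_params(tic: Tic, config: RunConfig | None = None) -> HeuristicParams:
    """Heuristic bolus descriptors of one preprocessed TIC."""
    res = heuristic_params_matrix(tic.t, tic.y[:, None], config)
    PI = float(res["PI"][0])
    if not np.isfinite(PI) or PI <= 0:
        return HeuristicParams(np.nan, np.nan, np.nan, np.nan, valid=False)
    return HeuristicParams(AT=float(res["AT"][0]), PT=float(res["PT"][0]),
                           PI=PI, WIT=float(res["WIT"][0]), valid=True)


# ---------------------------------------------------------------------------
# LDRW fitting
# ---------------------------------------------------------------------------


def _initial_guess(t: np.ndarray, y: np.ndarray,
                   config: RunConfig | None = None) -> tuple[np.ndarray, float]:
    h = heuristic_params_matrix(t, y[:, None], config)
    AT = float(h["AT"][0])
    if not np.isfinite(AT):
        AT = float(t[0])
    t0 = max(AT - 1.0, 0.0)
    w = np.clip(y, 0.0, None)
    area = float(np.trapezoid(w, t))
    tau = np.clip(t - t0, 1e-6, None)
    if w.sum() > 0:
        mu = float(np.sum(tau * w) / np.sum(w))
        var = float(np.sum((tau - mu) ** 2 * w) / np.sum(w))
    else:
        mu, var = 10.0, 10.0
    mu = float(np.clip(mu, 1e-2, t[-1]))
    kappa = float(np.clip(mu / max(var, 1e-6), 1e-3, 1e3))
    alpha = max(area, 1e-9)
    return np.array([alpha, kappa, mu, t0]), AT


def fit_ldrw(tic: Tic, config: RunConfig | None = None) -> LdrwFit:
    """Nonlinear least-squares fit of the LDRW model to a preprocessed TIC.

    Initialization comes from curve moments; ``t0`` is a free parameter
    bounded within ``[0, AT]``.  The fit is flagged unconverged when the
    optimizer fails or a shape parameter ends at its bound.
    """
    t, y = tic.t, tic.y
    if not tic.valid or len(t) < 8 or not np.any(y > 0):
        return LdrwFit(np.nan, np.nan, np.nan, np.nan, 0.0, np.nan, False)
    x0, AT = _initial_guess(t, y, config)
    lo = np.array([1e-9, 1e-4, 1e-3, 0.0])
    hi = np.array([np.inf, 1e3, float(t[-1]), max(AT, 1e-3)])
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isfinite(hi), hi - 1e-12, x0 + 1.0))

    def resid(x: np.ndarray) -> np.ndarray:
        return ldrw_model(t, *x) - y

    def jac(x: np.ndarray) -> np.ndarray:
        return _ldrw_jacobian(t, *x)

    try:
        res = optimize.least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf",
            ftol=1e-8, xtol=1e-10, gtol=1e-10, max_nfev=500,
            x_scale=np.maximum(np.abs(x0), 1e-3),
        )
    except Exception:
        return LdrwFit(np.nan, np.nan, np.nan, np.nan, 0.0, np.nan, False)
    alpha, kappa, mu, t0 = res.x
    rss = float(2.0 * res.cost)
    at_bound = (
        kappa <= lo[1] * (1 + 1e-9) or kappa >= hi[1] * (1 - 1e-9)
        or mu <= lo[2] * (1 + 1e-9) or mu >= hi[2] * (1 - 1e-9)
        or alpha <= lo[0] * (1 + 1e-9)
    )
    converged = bool(res.success) and not at_bound
    return LdrwFit(mu=float(mu), kappa=float(kappa), alpha=float(alpha),
                   t0=float(t0), baseline=0.0, rss=rss, converged=converged)


# ---------------------------------------------------------------------------
# per-plane maps
# ---------------------------------------------------------------------------


def tic_maps(dce: DcePlane, prostate_mask: np.ndarray,
             config: RunConfig | None = None) -> dict[str, ParamMap]:
    """Fit every in-mask pixel's TIC and return the seven kinetic maps
    ``mu, kappa, alpha, AT, PT, PI, WIT``.

    Pixels whose fit does not converge are flagged invalid in the model-based
    maps; heuristic maps are invalid where the smoothed curve has zero peak.
    Deterministic given the loop and configuration.
    """
    cfg = config or RunConfig()
    shape = dce.frame_shape
    mask = np.asarray(prostate_mask, dtype=bool)
    maps = {name: np.full(shape, np.nan) for name in TIC_MAP_NAMES}
    rows, cols = np.nonzero(mask)
    if len(rows) > 0:
        t = dce.timestamps
        Y = preprocess_curves(t, dce.frames[:, rows, cols].astype(float), cfg)
        heur = heuristic_params_matrix(t, Y, cfg)
        for name in ("AT", "PT", "PI", "WIT"):
            maps[name][rows, cols] = heur[name]
        for k in range(len(rows)):
            fit = fit_ldrw(Tic(t, Y[:, k], (int(rows[k]), int(cols[k]))), cfg)
            if fit.converged:
                maps["mu"][rows[k], cols[k]] = fit.mu
                maps["kappa"][rows[k], cols[k]] = fit.kappa
                maps["alpha"][rows[k], cols[k]] = fit.alpha
    return {
        name: ParamMap(name=name, values=maps[name], valid=np.isfinite(maps[name]),
                       units=BASE_UNITS[name])
        for name in TIC_MAP_NAMES
    }
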