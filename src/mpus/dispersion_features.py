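"""Neighborhood-based contrast dispersion and perfusion estimators.

Contrast transport through the microvasculature is treated as a
convective-dispersive process.  Around each pixel, a ring of neighbors
(default 0.5-2.0 mm) provides three families of estimates:

* **spatiotemporal correlation** ``r`` — mean zero-lag Pearson correlation
  between the center TIC and each ring TIC over the bolus-transit window;
* **spectral coherence** ``rho`` — mean magnitude-squared coherence in the
  sub-0.5-Hz band where bolus kinetics live;
* **local system identification** — the impulse response from the center to
  each neighbor is estimated by Tikhonov-regularized least-squares
  deconvolution and jointly fitted with the 1-D convection-dispersion
  Green's function

      g(t; d, v, D) = d / sqrt(4 pi D t^3) * exp(-(d - v t)^2 / (4 D t))

  yielding the contrast velocity ``v`` (mm/s), dispersion ``D`` (mm^2/s) and
  Peclet number ``Pe = v L / D`` with ``L`` the mean neighbor distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, signal

from mpus.data_model import BASE_UNITS, DcePlane, ParamMap, RunConfig, ring_offsets
from mpus.tic_features import Tic, heuristic_params_matrix, preprocess_curves

DISPERSION_MAP_NAMES = ("v", "D", "Pe", "r", "rho")


@dataclass
class ConvDispEstimate:
    v: float
    D: float
    Pe: float
    residual: float
    valid: bool
    length_scale_mm: float = np.nan


# ---------------------------------------------------------------------------
# similarity estimators
# ---------------------------------------------------------------------------


def _transit_window(t: np.ndarray, center: np.ndarray,
                    config: RunConfig) -> np.ndarray:
    """Boolean sample window AT-5 s .. AT+60 s (clipped to the record)."""
    h = heuristic_params_matrix(t, center[:, None], config)
    at = float(h["AT"][0])
    if not np.isfinite(at):
        return np.ones_like(t, dtype=bool)
    return (t >= at - config.corr_window_pre_s) & (t <= at + config.corr_window_post_s)


def _mean_pearson(center: np.ndarray, neighbors: np.ndarray) -> float:
    """Mean Pearson correlation of ``center`` (n,) against rows of
    ``neighbors`` (m, n); zero-variance neighbors are excluded."""
    c = center - center.mean()
    cs = np.sqrt((c * c).sum())
    if cs == 0:
        return np.nan
    X = neighbors - neighbors.mean(axis=1, keepdims=True)
    xs = np.sqrt((X * X).sum(axis=1))
    ok = xs > 0
    if not ok.any():
        return np.nan
    return float(np.mean((X[ok] @ c) / (xs[ok] * cs)))


def spatiotemporal_correlation(center: Tic, neighbors: Sequence[Tic],
                               config: RunConfig | None = None) -> float:
    """Mean zero-lag Pearson correlation between the center TIC and each
    neighbor over the bolus-transit window; NaN for a flat center."""
    cfg = config or RunConfig()
    w = _transit_window(center.t, center.y, cfg)
    nb = np.stack([n.y for n in neighbors], axis=0)
    return _mean_pearson(center.y[w], nb[:, w])


def _stft_segments(Y: np.ndarray, nperseg: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, per-segment-detrended rFFT segments (Welch, 50 %
    overlap) of a (time, pixel) matrix.  Returns (Z, f_norm) with ``Z`` of
    shape (n_seg, n_freq, n_pixel) and ``f_norm`` the frequencies in cycles
    per sample."""
    T = Y.shape[0]
    nperseg = min(nperseg, T)
    step = nperseg // 2
    starts = range(0, T - nperseg + 1, step)
    win = signal.get_window("hann", nperseg)
    segs = []
    for s in starts:
        seg = Y[s:s + nperseg]
        seg = seg - seg.mean(axis=0, keepdims=True)
        segs.append(np.fft.rfft(win[:, None] * seg, axis=0))
    return np.stack(segs, axis=0), np.fft.rfftfreq(nperseg)


def _band_coherence_pairs(Zc: np.ndarray, Zn: np.ndarray,
                          band: np.ndarray) -> np.ndarray:
    """In-band mean magnitude-squared coherence for paired segment spectra
    ``Zc``/``Zn`` of shape (n_seg, n_freq, n_pair)."""
    Pcc = np.mean(np.abs(Zc) ** 2, axis=0)
    Pnn = np.mean(np.abs(Zn) ** 2, axis=0)
    Pcn = np.mean(Zc * np.conj(Zn), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(Pcn) ** 2 / (Pcc * Pnn)
    return np.mean(C[band], axis=0)


def spectral_coherence(center: Tic, neighbors: Sequence[Tic],
                       config: RunConfig | None = None) -> float:
    """Mean in-band magnitude-squared coherence (Welch segments, 50 %
    overlap) between the center TIC and its neighbors; NaN for flat
    curves.  The band defaults to 0-0.5 Hz, where bolus kinetics live."""
    cfg = config or RunConfig()
    if len(center.t) < 64:
        raise ValueError("spectral coherence requires at least 64 samples")
    if center.y.std() == 0:
        return np.nan
    fs = 1.0 / float(np.median(np.diff(center.t)))
    Y = np.stack([center.y] + [n.y for n in neighbors], axis=1)
    Z, f_norm = _stft_segments(Y, cfg.coherence_nperseg)
    f = f_norm * fs
    band = (f >= cfg.coherence_band_hz[0]) & (f <= cfg.coherence_band_hz[1])
    if not band.any():
        band = np.ones_like(f, dtype=bool)
    m = Y.shape[1] - 1
    vals = _band_coherence_pairs(np.repeat(Z[:, :, :1], m, axis=2), Z[:, :, 1:], band)
    if not np.all(np.isfinite(vals)):
        return np.nan
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# convection-dispersion identification
# ---------------------------------------------------------------------------


def greens_function(t: np.ndarray, d_mm, v: float, D: float) -> np.ndarray:
    """Impulse response of 1-D convection-dispersion transport over distance
    ``d_mm`` (scalar or array, broadcast against ``t``); zero at t <= 0."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d_mm, dtype=float)
    if d.ndim > 0:
        d = d[:, None]
    pos = t > 1e-12
    tp = np.where(pos, t, 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        out = d / np.sqrt(4.0 * np.pi * D * tp ** 3) * np.exp(
            -((d - v * tp) ** 2) / (4.0 * D * tp)
        )
    return np.where(pos, out, 0.0)


def _deconvolve(center: np.ndarray, neighbors: np.ndarray, dt: float,
                n_taps: int, lam_rel: float) -> tuple[np.ndarray, np.ndarray]:
    """Tikhonov-regularized LS impulse responses center -> each neighbor.

    Solves ``(C'C + lam I) h = C'y`` with ``C`` the (causal) convolution
    matrix of the center curve and ``lam = lam_rel * trace(C'C) / n_taps``.
    Returns ``(H, S)`` where ``H`` is (m, n_taps) and ``S`` the resolution
    operator ``(C'C + lam I)^-1 C'C`` that maps a true impulse response to
    its regularized estimate.  Candidate model responses are passed through
    ``S`` before comparison with ``H``, which keeps the downstream
    Green's-function fit unbiased by the regularization.
    """
    T = len(center)
    L = min(n_taps, T)
    C = linalg.toeplitz(center, np.zeros(L)) * dt
    G0 = C.T @ C
    G = G0.copy()
    lam = lam_rel * np.trace(G0) / L
    G[np.diag_indices_from(G)] += lam
    rhs = C.T @ neighbors.T  # (L, m)
    cho = linalg.cho_factor(G, check_finite=False)
    H = linalg.cho_solve(cho, rhs, check_finite=False).T
    S = linalg.cho_solve(cho, G0, check_finite=False)
    return H, S


def identify_conv_disp(center: Tic,
                       neighbors: Sequence[tuple[Tic, float]],
                       config: RunConfig | None = None) -> ConvDispEstimate:
    """Estimate (v, D, Pe) from the center TIC and ring neighbors.

    Impulse responses are deconvolved per neighbor, then the
    convection-dispersion Green's function is fitted jointly across neighbors
    by nonlinear least squares over ``(v, D)`` with one shared amplitude
    factor absorbing the regularization-induced gain loss.
    """
    cfg = config or RunConfig()
    if len(neighbors) < cfg.min_ring_members:
        return ConvDispEstimate(np.nan, np.nan, np.nan, np.nan, False)
    t = center.t
    dt = float(np.median(np.diff(t)))
    if center.y.std() == 0 or not np.any(center.y > 0):
        return ConvDispEstimate(np.nan, np.nan, np.nan, np.nan, False)
    nb = np.stack([n.y for n, _ in neighbors], axis=0)
    dists = np.array([d for _, d in neighbors], dtype=float)
    n_taps = max(4, int(round(cfg.impulse_support_s / dt)))
    H, S = _deconvolve(center.y, nb, dt, n_taps, cfg.tikhonov_lambda)
    tau = np.arange(H.shape[1]) * dt
    L_mm = float(dists.mean())

    lo = np.array([1e-3, 1e-5, 1e-6])
    hi = np.array([50.0, 50.0, 1e6])

    def _smodel(v: float, D: float) -> np.ndarray:
        return greens_function(tau, dists, v, D) @ S.T

    # transport is identified from neighbors with a resolvable causal delay,
    # estimated by cross-correlation of the raw curves (the regularized
    # impulse response is too smeared to localize the delay).  Under
    # directional flow, upstream neighbors lead the center and carry no
    # causal center->neighbor response; an all-zero-lag ring means the
    # delay is unresolvable at this frame rate.
    T = len(center.y)
    max_lag = min(H.shape[1] - 1, T - 1)
    c0 = center.y - center.y.mean()
    nbc = nb - nb.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    cc = np.fft.irfft(np.fft.rfft(nbc, nfft, axis=1)
                      * np.conj(np.fft.rfft(c0, nfft)), nfft, axis=1)
    # circular correlation: lag k at column k, lag -k at column nfft-k
    window = np.concatenate([cc[:, nfft - max_lag:], cc[:, :max_lag + 1]], axis=1)
    delays = (np.argmax(window, axis=1) - max_lag) * dt
    resolvable = delays > dt / 2
    if resolvable.sum() < 4:
        return ConvDispEstimate(np.nan, np.nan, np.nan, np.nan, False)
    H = H[resolvable]
    dists = dists[resolvable]
    L_mm = float(dists.mean())
    v_peak = float(np.median(dists / delays[resolvable]))

    # coarse screen over (v, D) with the amplitude solved in closed form,
    # seeded additionally by the impulse-response peak delays
    v_cand = np.unique(np.clip(np.concatenate([
        np.geomspace(0.1, 8.0, 12), [v_peak]]), 0.05, 40.0))
    D_cand = np.geomspace(0.02, 2.0, 8)
    cands = []
    hh = float((H * H).sum())
    for vc in v_cand:
        for Dc in D_cand:
            M = _smodel(vc, Dc)
            mm = float((M * M).sum())
            if mm <= 0:
                continue
            a = float(np.clip((M * H).sum() / mm, 1e-6, 1e6))
            sse = hh - 2 * a * float((M * H).sum()) + a * a * mm
            cands.append((sse, vc, Dc, a))
    if not cands:
        return ConvDispEstimate(np.nan, np.nan, np.nan, np.nan, False)
    cands.sort(key=lambda c: c[0])
    starts, seen_v = [], []
    for sse, vc, Dc, a in cands:  # top candidates at distinct velocities
        if all(abs(np.log(vc / sv)) > 0.3 for sv in seen_v):
            starts.append((vc, Dc, a))
            seen_v.append(vc)
        if len(starts) == 2:
            break

    def resid(x: np.ndarray) -> np.ndarray:
        v, D, a = x
        return (a * _smodel(v, D) - H).ravel()

    def jac(x: np.ndarray) -> np.ndarray:
        v, D, a = x
        g = greens_function(tau, dists, v, D)
        dd = dists[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = np.where(tau > 1e-12, tau, 1.0)
            dgdv = g * (dd - v * tp) / (2.0 * D)
            dgdD = g * (-0.5 / D + (dd - v * tp) ** 2 / (4.0 * D * D * tp))
        J = np.empty((H.size, 3))
        J[:, 0] = (a * (dgdv @ S.T)).ravel()
        J[:, 1] = (a * (dgdD @ S.T)).ravel()
        J[:, 2] = (g @ S.T).ravel()
        return J

    res = None
    for v0, D0, a0 in starts:
        try:
            cand = optimize.least_squares(
                resid, np.clip([v0, D0, a0], lo + 1e-12, hi - 1e-12),
                jac=jac, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-10, max_nfev=250,
                x_scale=[max(v0, 0.1), max(D0, 0.01), max(abs(a0), 0.1)],
            )
        except Exception:
            continue
        if res is None or cand.cost < res.cost:
            res = cand
    if res is None:
        return ConvDispEstimate(np.nan, np.nan, np.nan, np.nan, False)
    v, D, _ = res.x
    at_bound = (v >= hi[0] * (1 - 1e-6) or D <= lo[1] * (1 + 1e-6)
                or D >= hi[1] * (1 - 1e-6))
    if not res.success or at_bound:
        return ConvDispEstimate(np.nan, np.nan, np.nan, float(2 * res.cost), False)
    pe = v * L_mm / D
    return ConvDispEstimate(v=float(v), D=float(D), Pe=float(pe),
                            residual=float(2 * res.cost), valid=True,
                            length_scale_mm=L_mm)


# ---------------------------------------------------------------------------
# per-plane maps
# ---------------------------------------------------------------------------


def dispersion_maps(dce: DcePlane, prostate_mask: np.ndarray,
                    config: RunConfig | None = None) -> dict[str, ParamMap]:
    """Per-pixel v, D, Pe, r and rho maps over the prostate mask.

    The ring kernel defaults to 0.5-2.0 mm; pixels whose ring retains fewer
    than ``min_ring_members`` in-mask neighbors are invalid.
    """
    cfg = config or RunConfig()
    mask = np.asarray(prostate_mask, dtype=bool)
    shape = dce.frame_shape
    out = {name: np.full(shape, np.nan) for name in DISPERSION_MAP_NAMES}
    rows, cols = np.nonzero(mask)
    if len(rows) > 0:
        t = dce.timestamps
        n_px = len(rows)
        Y = preprocess_curves(t, dce.frames[:, rows, cols].astype(float), cfg)
        idx_map = np.full(shape, -1, dtype=int)
        idx_map[rows, cols] = np.arange(n_px)
        offs, dists_mm = ring_offsets(cfg.ring_inner_mm, cfg.ring_outer_mm,
                                      dce.pixel_spacing, cfg.ring_max_members)
        heur = heuristic_params_matrix(t, Y, cfg)
        fs = 1.0 / float(np.median(np.diff(t)))
        long_enough = len(t) >= 64

        # neighbor index per (offset, pixel); -1 where outside the mask
        nb_of = np.full((len(offs), n_px), -1, dtype=int)
        for j, (dr, dc) in enumerate(offs):
            rr, cc = rows + dr, cols + dc
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            nb_of[j, ok] = idx_map[rr[ok], cc[ok]]
        n_members = (nb_of >= 0).sum(axis=0)
        enough = n_members >= cfg.min_ring_members

        # bolus-transit window per pixel (AT-5 s .. AT+60 s)
        at = heur["AT"]
        at_f = np.where(np.isfinite(at), at, t[0] + cfg.corr_window_pre_s)
        W = ((t[:, None] >= at_f[None, :] - cfg.corr_window_pre_s)
             & (t[:, None] <= at_f[None, :] + cfg.corr_window_post_s)).astype(float)

        # spatiotemporal correlation r, vectorized per ring offset
        r_sum = np.zeros(n_px)
        r_cnt = np.zeros(n_px, dtype=int)
        nW = W.sum(axis=0)
        mc = (Y * W).sum(axis=0) / nW
        Yc0 = (Y - mc[None, :]) * W                   # centered, windowed center
        var_c = (Yc0 * Yc0).sum(axis=0)
        for j in range(len(offs)):
            pair = np.nonzero(nb_of[j] >= 0)[0]
            if len(pair) == 0:
                continue
            nb = nb_of[j, pair]
            Yn = Y[:, nb]
            Wp = W[:, pair]
            mn = (Yn * Wp).sum(axis=0) / nW[pair]
            Yn0 = (Yn - mn[None, :]) * Wp
            var_n = (Yn0 * Yn0).sum(axis=0)
            cov = (Yc0[:, pair] * Yn0).sum(axis=0)
            good = (var_c[pair] > 0) & (var_n > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rv = cov / np.sqrt(var_c[pair] * var_n)
            r_sum[pair[good]] += rv[good]
            r_cnt[pair[good]] += 1
        has_r = enough & (r_cnt > 0) & (var_c > 0)
        out["r"][rows[has_r], cols[has_r]] = r_sum[has_r] / r_cnt[has_r]

        # spectral coherence rho, vectorized with shared Welch segments
        if long_enough:
            Z, f_norm = _stft_segments(Y, cfg.coherence_nperseg)
            f = f_norm * fs
            band = (f >= cfg.coherence_band_hz[0]) & (f <= cfg.coherence_band_hz[1])
            if not band.any():
                band = np.ones_like(f, dtype=bool)
            rho_sum = np.zeros(n_px)
            rho_cnt = np.zeros(n_px, dtype=int)
            for j in range(len(offs)):
                pair = np.nonzero(nb_of[j] >= 0)[0]
                if len(pair) == 0:
                    continue
                vals = _band_coherence_pairs(Z[:, :, pair], Z[:, :, nb_of[j, pair]],
                                             band)
                good = np.isfinite(vals)
                rho_sum[pair[good]] += vals[good]
                rho_cnt[pair[good]] += 1
            has_rho = enough & (rho_cnt > 0) & (Y.std(axis=0) > 0)
            out["rho"][rows[has_rho], cols[has_rho]] = (
                rho_sum[has_rho] / np.maximum(rho_cnt[has_rho], 1))

        # convective velocity / dispersion / Peclet by system identification
        for k in np.nonzero(enough)[0]:
            nb_idx = nb_of[:, k]
            sel = nb_idx >= 0
            nb = Y[:, nb_idx[sel]].T
            nb_d = dists_mm[sel]
            est = identify_conv_disp(
                Tic(t, Y[:, k]),
                [(Tic(t, nb[j]), float(nb_d[j])) for j in range(len(nb_d))],
                cfg,
            )
            if est.valid:
                out["v"][rows[k], cols[k]] = est.v
                out["D"][rows[k], cols[k]] = est.D
                out["Pe"][rows[k], cols[k]] = est.Pe
    return {
        name: ParamMap(name=name, values=out[name], valid=np.isfinite(out[name]),
                       units=BASE_UNITS[name])
        for name in DISPERSION_MAP_NAMES
    }
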