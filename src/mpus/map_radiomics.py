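"""Radiomic derivatives of parametric maps and B-mode calcification detection.

Each base parametric map spawns five spatial derivatives capturing
intra-prostate asymmetry and heterogeneity:

* ``name.rel``  — value minus the per-image median over valid in-mask pixels;
* ``name.entK`` — Shannon entropy (bits) of the value histogram in a circular
  kernel of radius K mm (K = 1, 2, 3 by default);
* ``name.var2`` — unbiased sample variance in a 2-mm circular kernel.

Histogram bin edges for the entropy are fixed per image over the robust
1st-99th percentile range of the valid in-mask values; values outside the
range fall into the first/last bin.  Calcifications are detected as
hyperechoic B-mode spots: the image is convolved with 2-D Gaussians of
sigma 0.6 mm and 1.8 mm (matched to spot diameters of roughly 1.2 and
3.6 mm), each response is thresholded 3 robust standard deviations
(median + 3 x 1.4826 MAD) above the in-mask response median, the union is
gated by the same robust threshold on the raw image, and small components
are discarded.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from mpus.data_model import (
    BASE_FEATURES,
    DERIVATIVE_SUFFIXES,
    ParamMap,
    RunConfig,
    disk_offsets,
    radius_mm_to_px,
)

# ---------------------------------------------------------------------------
# neighborhood machinery
# ---------------------------------------------------------------------------


def _neighborhood_stack(values: np.ndarray, offsets: np.ndarray,
                        row_slice: slice) -> np.ndarray:
    """(n_offsets, rows, cols) stack of kernel members for a band of rows;
    out-of-image members are NaN."""
    H, W = values.shape
    r = int(np.abs(offsets).max())
    padded = np.full((H + 2 * r, W + 2 * r), np.nan)
    padded[r:r + H, r:r + W] = values
    r0, r1 = row_slice.start, row_slice.stop
    n = len(offsets)
    out = np.empty((n, r1 - r0, W))
    for i, (dr, dc) in enumerate(offsets):
        out[i] = padded[r0 + r + dr:r1 + r + dr, r + dc:r + dc + W]
    return out


def _kernel_reduce(values: np.ndarray, offsets: np.ndarray, func,
                   chunk_rows: int = 48) -> np.ndarray:
    """Apply ``func`` (acting on axis 0 of a member stack) over a circular
    kernel at every pixel, NaN-aware, in row bands to bound memory."""
    H, W = values.shape
    out = np.empty((H, W))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r0 in range(0, H, chunk_rows):
            sl = slice(r0, min(r0 + chunk_rows, H))
            stack = _neighborhood_stack(values, offsets, sl)
            out[sl] = func(stack)
    return out


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def relative_to_median(pmap: ParamMap, prostate_mask: np.ndarray,
                       config: RunConfig | None = None) -> ParamMap:
    """Map value relative to the per-image median of valid in-mask values.

    Difference by default; ratio mode (config) requires a nonzero median and
    is meant for strictly positive maps.
    """
    cfg = config or RunConfig()
    mask = np.asarray(prostate_mask, dtype=bool)
    valid = pmap.valid & mask
    out = np.full(pmap.values.shape, np.nan)
    if valid.any():
        med = float(np.median(pmap.values[valid]))
        if cfg.relative_mode == "ratio":
            if med == 0:
                raise ValueError("ratio relative mode undefined for zero median")
            out[valid] = pmap.values[valid] / med
        else:
            out[valid] = pmap.values[valid] - med
    return ParamMap(name=pmap.name + ".rel", values=out, valid=np.isfinite(out),
                    units=pmap.units if cfg.relative_mode == "difference" else "-")


def entropy_bin_edges(values: np.ndarray, valid: np.ndarray, bins: int) -> np.ndarray:
    """Per-image histogram edges over the robust 1-99 percentile range."""
    v = values[valid]
    lo, hi = np.percentile(v, [1.0, 99.0])
    if hi <= lo:
        return np.array([lo, lo])  # degenerate: single bin
    return np.linspace(lo, hi, bins + 1)


def bin_assignments(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value: half-open bins, out-of-range values clipped into
    the first/last bin."""
    nb = max(len(edges) - 1, 1)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, nb - 1)


def local_entropy(pmap: ParamMap, radius_mm: float,
                  pixel_spacing: float | tuple[float, float],
                  config: RunConfig | None = None,
                  min_members: int = 10) -> ParamMap:
    """Shannon entropy (bits) of valid values in a circular kernel.

    Bin counts are obtained by convolving per-bin indicator maps with the
    disk kernel; pixels with fewer than ``min_members`` valid members, or
    invalid in the base map, are invalid.
    """
    cfg = config or RunConfig()
    name = f"{pmap.name}.ent{int(round(radius_mm))}"
    out = np.full(pmap.values.shape, np.nan)
    valid = pmap.valid
    if valid.any():
        r_px = radius_mm_to_px(radius_mm, pixel_spacing)
        offs = disk_offsets(r_px)
        kernel = np.zeros((2 * r_px + 1, 2 * r_px + 1))
        kernel[offs[:, 0] + r_px, offs[:, 1] + r_px] = 1.0
        edges = entropy_bin_edges(pmap.values, valid, cfg.entropy_bins)
        n_bins = max(len(edges) - 1, 1)
        bi = bin_assignments(np.nan_to_num(pmap.values), edges)
        counts = np.empty((n_bins,) + pmap.values.shape)
        for b in range(n_bins):
            ind = ((bi == b) & valid).astype(float)
            counts[b] = np.round(signal.fftconvolve(ind, kernel, mode="same"))
        counts = np.clip(counts, 0.0, None)
        total = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / total
            plogp = np.where(counts > 0, p * np.log2(p), 0.0)
            ent = -plogp.sum(axis=0)
        ok = valid & (total >= min_members)
        out[ok] = ent[ok]
    return ParamMap(name=name, values=out, valid=np.isfinite(out), units="bits")


def local_variance(pmap: ParamMap,
                   pixel_spacing: float | tuple[float, float],
                   config: RunConfig | None = None) -> ParamMap:
    """Unbiased sample variance of valid values in the 2-mm circular kernel;
    invalid with fewer than 2 valid members or where the base is invalid."""
    cfg = config or RunConfig()
    name = f"{pmap.name}.var{int(round(cfg.variance_radius_mm))}"
    out = np.full(pmap.values.shape, np.nan)
    if pmap.valid.any():
        r_px = radius_mm_to_px(cfg.variance_radius_mm, pixel_spacing)
        offs = disk_offsets(r_px)

        def _var(stack: np.ndarray) -> np.ndarray:
            n = np.sum(np.isfinite(stack), axis=0)
            v = np.nanvar(stack, axis=0, ddof=1)
            return np.where(n >= 2, v, np.nan)

        var = _kernel_reduce(pmap.values, offs, _var)
        ok = pmap.valid & np.isfinite(var)
        out[ok] = var[ok]
    return ParamMap(name=name, values=out, valid=np.isfinite(out),
                    units=f"({pmap.units})^2" if pmap.units not in ("", "-") else "-")


def detect_calcifications(bmode: np.ndarray, prostate_mask: np.ndarray,
                          pixel_spacing: float | tuple[float, float],
                          config: RunConfig | None = None) -> np.ndarray:
    """Detect hyperechoic (bright) spots in the fundamental B-mode image.

    Two Gaussian-smoothed responses (sigma 0.6 and 1.8 mm) act as matched
    filters for spots of ~1.2 and ~3.6 mm diameter; each is thresholded
    ``calc_threshold_nsd`` robust SDs (1.4826 MAD) above the in-mask
    response median.  The union is intersected with a raw-amplitude gate at
    the same robust level — the smoothing skirt around a bright spot exceeds
    the response threshold but not the raw one — and cleaned of components
    smaller than ``calc_min_component_px``.  Dark (hypoechoic) spots are
    never flagged.
    """
    cfg = config or RunConfig()
    img = np.asarray(bmode, dtype=float)
    mask = np.asarray(prostate_mask, dtype=bool)
    spacing = float(np.mean(pixel_spacing))
    detected = np.zeros(img.shape, dtype=bool)
    if not mask.any():
        return detected

    def _robust_threshold(values: np.ndarray) -> float | None:
        center = float(np.median(values))
        sd = 1.4826 * float(np.median(np.abs(values - center)))
        if sd <= 1e-9 * max(abs(center), 1.0):
            return None  # featureless: nothing stands out
        return center + cfg.calc_threshold_nsd * sd

    for sigma_mm in cfg.calc_sigmas_mm:
        resp = ndimage.gaussian_filter(img, sigma=sigma_mm / spacing)
        thr = _robust_threshold(resp[mask])
        if thr is not None:
            detected |= mask & (resp > thr)
    raw_thr = _robust_threshold(img[mask])
    if raw_thr is None:
        return np.zeros(img.shape, dtype=bool)
    detected &= img > raw_thr
    if detected.any() and cfg.calc_min_component_px > 1:
        lab, n = ndimage.label(detected)
        sizes = np.bincount(lab.ravel())
        kill = np.nonzero(sizes < cfg.calc_min_component_px)[0]
        detected[np.isin(lab, kill)] = False
    return detected


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


def radiomic_expand(base_maps: dict[str, ParamMap], prostate_mask: np.ndarray,
                    pixel_spacing: float | tuple[float, float],
                    config: RunConfig | None = None) -> dict[str, ParamMap]:
    """Expand base maps into the full manifest-ordered feature-map set.

    Every base map yields ``value, rel, ent1, ent2, ent3, var2``; with the
    standard 14-map catalog that is 84 feature maps.  Input order is
    irrelevant: the output follows the canonical manifest.  A pixel invalid
    in a base map is invalid in all its derivatives.
    """
    cfg = config or RunConfig()
    mask = np.asarray(prostate_mask, dtype=bool)
    shapes = {m.values.shape for m in base_maps.values()} | {mask.shape}
    if len(shapes) > 1:
        raise ValueError(f"base maps must share one pixel grid, got {shapes}")
    ordered = [n for n in BASE_FEATURES if n in base_maps]
    extras = [n for n in base_maps if n not in BASE_FEATURES]
    out: dict[str, ParamMap] = {}
    for name in ordered + sorted(extras):
        base = base_maps[name]
        clipped = ParamMap(name=base.name, values=base.values,
                           valid=base.valid & mask, units=base.units)
        out[name] = clipped
        out[name + ".rel"] = relative_to_median(clipped, mask, cfg)
        if clipped.valid.any():
            for radius in cfg.entropy_radii_mm:
                ent = local_entropy(clipped, radius, pixel_spacing, cfg)
                out[ent.name] = ent
            var = local_variance(clipped, pixel_spacing, cfg)
            out[var.name] = var
        else:
            for radius in cfg.entropy_radii_mm:
                suffix = f".ent{int(round(radius))}"
                out[name + suffix] = ParamMap(
                    name=name + suffix, values=np.full(mask.shape, np.nan),
                    valid=np.zeros(mask.shape, bool), units="bits")
            vname = f"{name}.var{int(round(cfg.variance_radius_mm))}"
            out[vname] = ParamMap(name=vname, values=np.full(mask.shape, np.nan),
                                  valid=np.zeros(mask.shape, bool), units="-")
    expected_suffixes = [s for s in DERIVATIVE_SUFFIXES]
    ordered_names = [n + s for n in ordered + sorted(extras) for s in expected_suffixes]
    return {n: out[n] for n in ordered_names}
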