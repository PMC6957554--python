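"""Domain types and I/O for multiparametric ultrasound planes.

Shared vocabulary of the pipeline: the DCE-US cine loop (:class:`DcePlane`),
the co-registered per-plane raster bundle (:class:`PlaneBundle`), named
parametric maps (:class:`ParamMap`), the per-pixel feature table
(:class:`FeatureTable`) and the run configuration (:class:`RunConfig`).

Conventions
-----------
* Arrays are indexed ``(row, col)`` (and ``(time, row, col)`` for cine
  loops), 0-based, pixel centers; physical kernel sizes are given in mm and
  converted to pixels through ``pixel_spacing``.
* Invalid per-pixel estimates carry NaN and are excluded from medians,
  entropies and training — never silently zeroed.
* Masks are 8-bit label rasters: zone ``{0 outside, 1 PZ, 2 TZ}``, ROI
  ``{0 unlabeled, 1 benign, 2 malignant}``, booleans ``{0, 1}``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

# ---------------------------------------------------------------------------
# label codes
# ---------------------------------------------------------------------------

ZONE_OUTSIDE, ZONE_PZ, ZONE_TZ = 0, 1, 2
LABEL_UNLABELED, LABEL_BENIGN, LABEL_MALIGNANT = 0, 1, 2

ZONE_NAMES = {ZONE_OUTSIDE: "outside", ZONE_PZ: "PZ", ZONE_TZ: "TZ"}
LABEL_NAMES = {LABEL_UNLABELED: "unlabeled", LABEL_BENIGN: "benign", LABEL_MALIGNANT: "malignant"}

#: Base parametric maps, in canonical (manifest) order.  The first twelve are
#: DCE-US derived, ``E`` is the SWE Young's modulus (kPa) and ``G`` the
#: B-mode gray level.
BASE_FEATURES: tuple[str, ...] = (
    "Pe", "v", "D", "r", "rho", "kappa", "mu", "alpha",
    "WIT", "PT", "AT", "PI", "E", "G",
)

BASE_UNITS: dict[str, str] = {
    "Pe": "-", "v": "mm/s", "D": "mm^2/s", "r": "-", "rho": "-",
    "kappa": "1/s", "mu": "s", "alpha": "a.u.*s", "WIT": "s", "PT": "s",
    "AT": "s", "PI": "a.u.", "E": "kPa", "G": "gray level",
}

#: Radiomic derivative suffixes appended to each base map name.  The empty
#: suffix is the raw value; ``rel`` the value relative to the per-image
#: median; ``entK`` the local entropy at the K-mm kernel; ``var2`` the local
#: variance at the 2-mm kernel.
DERIVATIVE_SUFFIXES: tuple[str, ...] = ("", ".rel", ".ent1", ".ent2", ".ent3", ".var2")


def feature_catalog(base: Sequence[str] = BASE_FEATURES) -> list[str]:
    """Full feature manifest: every base map crossed with every derivative."""
    return [b + s for b in base for s in DERIVATIVE_SUFFIXES]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline, with physical units where relevant.

    Defaults reproduce the published recipe wherever it states a value
    (kernel radii, forest growing parameters, median-filter radius); the
    remaining values are documented conventions.
    """

    # geometry
    entropy_radii_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    variance_radius_mm: float = 2.0
    entropy_bins: int = 32
    ring_inner_mm: float = 0.5
    ring_outer_mm: float = 2.0
    ring_max_members: int = 12
    min_ring_members: int = 8

    # TIC preprocessing / heuristics
    baseline_window_s: float = 10.0
    lowpass_cutoff_hz: float = 0.5
    at_threshold_frac: float = 0.05
    wit_low_frac: float = 0.10
    wit_high_frac: float = 0.90

    # dispersion identification
    coherence_nperseg: int = 32
    coherence_band_hz: tuple[float, float] = (0.0, 0.5)
    tikhonov_lambda: float = 0.05
    impulse_support_s: float = 20.0
    corr_window_pre_s: float = 5.0
    corr_window_post_s: float = 60.0

    # calcification detection
    calc_sigmas_mm: tuple[float, ...] = (0.6, 1.8)
    calc_threshold_nsd: float = 3.0
    calc_min_component_px: int = 3

    # forest
    n_trees: int = 1000
    subsample_fraction: float = 1.0 / 1000.0
    min_tree_rows: int = 100
    balanced_bootstrap: bool = True
    patients_discarded_per_tree: int = 6
    max_depth: int = 50
    min_leaf: int = 5
    split_criterion: str = "entropy"  # cross-entropy / information gain
    median_filter_radius_px: int = 15

    # motion compensation
    moco_stride: int = 5
    moco_max_shift_mm: float = 5.0
    moco_max_rot_deg: float = 10.0
    reference_time_s: float = 30.0

    # misc
    dynamic_range_db: float = 40.0
    relative_mode: str = "difference"  # or "ratio" for strictly positive maps
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.entropy_radii_mm) or self.variance_radius_mm <= 0:
            raise ValueError("kernel radii must be positive")
        if not (0.0 < self.ring_inner_mm < self.ring_outer_mm):
            raise ValueError("ring kernel requires 0 < inner < outer radius")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.relative_mode not in ("difference", "ratio"):
            raise ValueError(f"unknown relative_mode {self.relative_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def radius_mm_to_px(radius_mm: float, pixel_spacing: float | tuple[float, float]) -> int:
    """Convert a physical kernel radius to pixels (nearest, at least 1)."""
    spacing = float(np.mean(pixel_spacing))
    if spacing <= 0:
        raise ValueError("pixel spacing must be positive")
    return max(1, int(round(radius_mm / spacing)))


def disk_offsets(radius_px: int) -> np.ndarray:
    """(n, 2) integer (drow, dcol) offsets of a filled circular kernel."""
    r = int(radius_px)
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dr * dr + dc * dc <= r * r
    return np.stack([dr[keep], dc[keep]], axis=1)


def ring_offsets(
    inner_mm: float,
    outer_mm: float,
    pixel_spacing: float | tuple[float, float],
    max_members: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets of an annular (ring) kernel and their distances in mm.

    When ``max_members`` is given, the ring is thinned deterministically to at
    most that many offsets, spread uniformly in polar angle, which keeps the
    per-pixel system-identification cost bounded on fine grids.
    """
    spacing = float(np.mean(pixel_spacing))
    r_out = int(np.ceil(outer_mm / spacing))
    dr, dc = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1]
    dist_mm = np.hypot(dr, dc) * spacing
    keep = (dist_mm >= inner_mm) & (dist_mm <= outer_mm)
    offs = np.stack([dr[keep], dc[keep]], axis=1)
    d = dist_mm[keep]
    if max_members is not None and len(offs) > max_members:
        ang = np.arctan2(offs[:, 0], offs[:, 1])
        order = np.lexsort((d, ang))
        pick = np.linspace(0, len(offs) - 1, max_members).round().astype(int)
        idx = order[pick]
        offs, d = offs[idx], d[idx]
    return offs, d


# ---------------------------------------------------------------------------
# intensity linearization
# ---------------------------------------------------------------------------


def linearize_intensity(frames: np.ndarray, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Undo display log-compression: ``10 ** (x * DR / (255 * 10))``.

    Maps gray level 0 to 1.0 and 255 to ``10 ** (DR / 10)``; model fitting
    requires linear echo-power amplitude, not display levels.
    """
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive (dB)")
    return np.power(10.0, np.asarray(frames, dtype=float) * dynamic_range_db / 2550.0)


def log_compress_intensity(frames: np.ndarray, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Inverse of :func:`linearize_intensity` (no quantization applied)."""
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive (dB)")
    x = np.asarray(frames, dtype=float)
    if np.any(x <= 0):
        raise ValueError("linear intensities must be positive for log compression")
    return 2550.0 * np.log10(x) / dynamic_range_db


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DcePlane:
    """A motion-susceptible DCE-US cine loop of one imaging plane.

    ``frames`` is ``(time, row, col)`` linear-amplitude intensity,
    ``timestamps`` are seconds from bolus injection (strictly increasing) and
    ``pixel_spacing`` is mm per pixel along (row, col).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_spacing: tuple[float, float]
    patient_id: str = ""
    plane_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, row, col) stack")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("frames must be non-negative after linearization")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PlaneBundle:
    """Co-registered rasters of one imaging plane of one patient."""

    dce: DcePlane
    bmode: np.ndarray
    swe: np.ndarray
    prostate_mask: np.ndarray
    zone_mask: np.ndarray
    calcification_mask: np.ndarray | None = None
    roi_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.dce.frame_shape
        self.bmode = np.asarray(self.bmode, dtype=float)
        self.swe = np.asarray(self.swe, dtype=float)
        self.prostate_mask = np.asarray(self.prostate_mask).astype(bool)
        self.zone_mask = np.asarray(self.zone_mask).astype(np.uint8)
        if self.calcification_mask is None:
            self.calcification_mask = np.zeros(shape, dtype=bool)
        self.calcification_mask = np.asarray(self.calcification_mask).astype(bool)
        if self.roi_labels is None:
            self.roi_labels = np.zeros(shape, dtype=np.uint8)
        self.roi_labels = np.asarray(self.roi_labels).astype(np.uint8)
        self.validate()

    def validate(self) -> None:
        shape = self.dce.frame_shape
        for role, arr in [
            ("bmode", self.bmode), ("swe", self.swe),
            ("prostate_mask", self.prostate_mask), ("zone_mask", self.zone_mask),
            ("calcification_mask", self.calcification_mask), ("roi_labels", self.roi_labels),
        ]:
            if arr.shape != shape:
                raise ValueError(
                    f"{role} shape {arr.shape} does not match DCE frame shape {shape}"
                )
        inside = self.prostate_mask
        if not np.all(np.isin(self.zone_mask[inside], (ZONE_PZ, ZONE_TZ))):
            raise ValueError("zone_mask must be PZ or TZ everywhere inside the prostate")
        if np.any(self.zone_mask[~inside] != ZONE_OUTSIDE):
            raise ValueError("zone_mask carries PZ/TZ labels outside the prostate mask")
        if np.any(self.roi_labels[~inside] != LABEL_UNLABELED):
            raise ValueError("ROI-labeled pixels must lie inside the prostate mask")

    @property
    def patient_id(self) -> str:
        return self.dce.patient_id

    @property
    def plane_id(self) -> str:
        return self.dce.plane_id


@dataclass
class ParamMap:
    """A named per-pixel feature map with validity mask and units."""

    name: str
    values: np.ndarray
    valid: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid).astype(bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share one shape")
        # invalid pixels carry NaN, never a silent zero
        self.values = np.where(self.valid, self.values, np.nan)

    @property
    def masked(self) -> np.ndarray:
        """Values with invalid pixels as NaN (alias for ``values``)."""
        return self.values


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

META_COLUMNS = ("patient_id", "plane_id", "row", "col", "zone", "label", "calcified")


class FeatureTable:
    """Per-pixel feature rows feeding the classifier.

    Wraps a :class:`pandas.DataFrame` whose metadata columns are
    ``patient_id, plane_id, row, col, zone, label, calcified`` followed by the
    feature columns in manifest order.  ``zone`` uses the PZ/TZ codes and
    ``label`` the benign/malignant/unlabeled codes of this module.
    """

    def __init__(self, df: pd.DataFrame, feature_columns: Sequence[str]):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing metadata columns {missing}")
        missing_f = [c for c in feature_columns if c not in df.columns]
        if missing_f:
            raise ValueError(f"feature table missing feature columns {missing_f}")
        if np.any(df["zone"].to_numpy() == ZONE_OUTSIDE):
            raise ValueError("feature table must not contain rows outside the prostate")
        self.feature_columns = list(feature_columns)
        self.df = df[list(META_COLUMNS) + self.feature_columns].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def features(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    def labeled(self, exclude_calcified: bool = False) -> "FeatureTable":
        """Rows with a benign/malignant label (optionally non-calcified only)."""
        m = self.df["label"].isin([LABEL_BENIGN, LABEL_MALIGNANT])
        if exclude_calcified:
            m &= ~self.df["calcified"].astype(bool)
        return FeatureTable(self.df[m].copy(), self.feature_columns)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df[np.asarray(mask)].copy(), self.feature_columns)

    @property
    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique().tolist())


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a leading manifest comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#manifest: " + ",".join(table.feature_columns) + "\n")
        table.df.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table, checking the stored manifest against the header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#manifest: "):
            raise ValueError("feature table file lacks a manifest line")
        manifest = first[len("#manifest: "):].strip()
        feature_columns = manifest.split(",") if manifest else []
        df = pd.read_csv(fh, dtype={"patient_id": str, "plane_id": str})
    data_cols = [c for c in df.columns if c not in META_COLUMNS]
    if data_cols != feature_columns:
        raise ValueError(
            f"feature columns {data_cols} do not match manifest {feature_columns}"
        )
    if len(df) == 0:
        df = df.astype({"row": int, "col": int, "zone": int, "label": int, "calcified": bool})
    return FeatureTable(df, feature_columns)


# ---------------------------------------------------------------------------
# plane bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_ROLES = (
    "dce", "meta", "bmode", "swe", "prostate_mask", "zone_mask",
    "calcification_mask", "roi_labels",
)


def _read_raster(path: Path) -> np.ndarray:
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj)
    return tifffile.imread(str(path))


def save_plane_bundle(bundle: PlaneBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as TIFF rasters plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dce": out_dir / "dce.tif",
        "meta": out_dir / "meta.json",
        "bmode": out_dir / "bmode.tif",
        "swe": out_dir / "swe.tif",
        "prostate_mask": out_dir / "prostate_mask.tif",
        "zone_mask": out_dir / "zone_mask.tif",
        "calcification_mask": out_dir / "calcification_mask.tif",
        "roi_labels": out_dir / "roi_labels.tif",
    }
    tifffile.imwrite(paths["dce"], bundle.dce.frames.astype(np.float32))
    tifffile.imwrite(paths["bmode"], bundle.bmode.astype(np.float32))
    tifffile.imwrite(paths["swe"], bundle.swe.astype(np.float32))
    tifffile.imwrite(paths["prostate_mask"], bundle.prostate_mask.astype(np.uint8))
    tifffile.imwrite(paths["zone_mask"], bundle.zone_mask.astype(np.uint8))
    tifffile.imwrite(paths["calcification_mask"], bundle.calcification_mask.astype(np.uint8))
    tifffile.imwrite(paths["roi_labels"], bundle.roi_labels.astype(np.uint8))
    meta = {
        "timestamps_s": bundle.dce.timestamps.tolist(),
        "pixel_spacing_mm": list(bundle.dce.pixel_spacing),
        "patient_id": bundle.dce.patient_id,
        "plane_id": bundle.dce.plane_id,
    }
    paths["meta"].write_text(json.dumps(meta))
    return paths


def load_plane_bundle(
    paths: Mapping[str, str | Path], config: RunConfig | None = None
) -> PlaneBundle:
    """Load and validate a plane bundle from a role -> path mapping.

    Required roles: ``dce, meta, bmode, swe, prostate_mask, zone_mask``;
    optional: ``calcification_mask, roi_labels``.  Raises on missing files or
    on rasters that do not share the DCE pixel grid — grids are never
    resampled silently.
    """
    required = ("dce", "meta", "bmode", "swe", "prostate_mask", "zone_mask")
    for role in required:
        if role not in paths:
            raise FileNotFoundError(f"bundle is missing required role {role!r}")
    for role, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"bundle file for role {role!r} not found: {p}")

    meta = json.loads(Path(paths["meta"]).read_text())
    frames = np.asarray(_read_raster(Path(paths["dce"])), dtype=np.float32)
    dce = DcePlane(
        frames=frames,
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        patient_id=str(meta.get("patient_id", "")),
        plane_id=str(meta.get("plane_id", "")),
    )
    kwargs: dict[str, np.ndarray] = {}
    for role in ("bmode", "swe", "prostate_mask", "zone_mask", "calcification_mask", "roi_labels"):
        if role in paths:
            kwargs[role] = _read_raster(Path(paths[role]))
    shapes = {role: arr.shape for role, arr in kwargs.items() if arr.shape != dce.frame_shape}
    if shapes:
        raise ValueError(
            f"rasters do not share the DCE grid {dce.frame_shape}: {shapes}"
        )
    return PlaneBundle(dce=dce, **kwargs)


def bundle_paths(plane_dir: str | Path) -> dict[str, Path]:
    """Standard role -> path mapping for a plane directory written by this package."""
    d = Path(plane_dir)
    names = {
        "dce": "dce.tif", "meta": "meta.json", "bmode": "bmode.tif", "swe": "swe.tif",
        "prostate_mask": "prostate_mask.tif", "zone_mask": "zone_mask.tif",
        "calcification_mask": "calcification_mask.tif", "roi_labels": "roi_labels.tif",
    }
    return {role: d / fname for role, fname in names.items() if (d / fname).exists() or role in
            ("dce", "meta", "bmode", "swe", "prostate_mask", "zone_mask")}
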