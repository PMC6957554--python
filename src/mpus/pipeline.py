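"""End-to-end feature extraction: plane bundle -> 84-column feature table.

Order of operations per plane: motion compensation of the DCE loop, kinetic
(TIC) maps, dispersion maps, stacking with the SWE and B-mode rasters into
the 14 base maps, calcification detection, and radiomic expansion into the
full manifest.  Rows cover every prostate pixel; ROI labels and the
calcification flag ride along as metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mpus import dispersion_features, map_radiomics, tic_features
from mpus.data_model import (
    BASE_UNITS,
    FeatureTable,
    ParamMap,
    PlaneBundle,
    RunConfig,
    feature_catalog,
)
from mpus.motion_compensation import compensate


def base_maps_for_bundle(bundle: PlaneBundle, config: RunConfig | None = None,
                         motion_compensate: bool = True) -> dict[str, ParamMap]:
    """The 14 base parametric maps of one plane."""
    cfg = config or RunConfig()
    dce = bundle.dce
    if motion_compensate and dce.n_frames >= 6:
        dce = compensate(dce, cfg).plane
    mask = bundle.prostate_mask
    maps = {}
    maps.update(tic_features.tic_maps(dce, mask, cfg))
    maps.update(dispersion_features.dispersion_maps(dce, mask, cfg))
    maps["E"] = ParamMap(name="E", values=np.where(mask, bundle.swe, np.nan),
                         valid=mask & np.isfinite(bundle.swe), units=BASE_UNITS["E"])
    maps["G"] = ParamMap(name="G", values=np.where(mask, bundle.bmode, np.nan),
                         valid=mask & np.isfinite(bundle.bmode), units=BASE_UNITS["G"])
    return maps


def extract_plane_features(bundle: PlaneBundle, config: RunConfig | None = None,
                           motion_compensate: bool = True
                           ) -> tuple[dict[str, ParamMap], pd.DataFrame]:
    """Feature maps and per-pixel rows (all prostate pixels) for one plane."""
    cfg = config or RunConfig()
    base = base_maps_for_bundle(bundle, cfg, motion_compensate)
    feats = map_radiomics.radiomic_expand(base, bundle.prostate_mask,
                                          bundle.dce.pixel_spacing, cfg)
    detected = map_radiomics.detect_calcifications(
        bundle.bmode, bundle.prostate_mask, bundle.dce.pixel_spacing, cfg)
    calcified = detected | bundle.calcification_mask

    rows, cols = np.nonzero(bundle.prostate_mask)
    df = pd.DataFrame({
        "patient_id": bundle.patient_id,
        "plane_id": bundle.plane_id,
        "row": rows.astype(int),
        "col": cols.astype(int),
        "zone": bundle.zone_mask[rows, cols].astype(int),
        "label": bundle.roi_labels[rows, cols].astype(int),
        "calcified": calcified[rows, cols],
    })
    for name, pm in feats.items():
        df[name] = pm.values[rows, cols]
    return feats, df


def extract_cohort_features(bundles: list[PlaneBundle],
                            config: RunConfig | None = None,
                            motion_compensate: bool = True) -> FeatureTable:
    """Concatenate per-plane feature rows of a cohort into one table."""
    cfg = config or RunConfig()
    frames = [extract_plane_features(b, cfg, motion_compensate)[1] for b in bundles]
    df = pd.concat(frames, ignore_index=True)
    return FeatureTable(df, feature_catalog())
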