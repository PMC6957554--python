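"""Ground-truth-bearing simulator of multiparametric ultrasound cohorts.

Each simulated plane carries a prostate ellipse with an inner transition
zone, one lesion per plane (alternating between PZ and TZ across the cohort
so that zone provenance stays balanced), and co-registered modalities:

* a DCE-US loop whose per-pixel TICs follow the LDRW bolus form with
  tissue-dependent parameters; bolus arrival propagates outward from a TZ
  inflow origin at the local contrast velocity, so neighboring TICs are
  delayed copies shaped by the local (v, D) field;
* an SWE Young's-modulus map (TZ stiffer than benign PZ, lesions stiffest);
* a speckled B-mode image with bright calcification spots;
* masks (prostate, zones, calcifications) and one unambiguously malignant
  plus one unambiguously benign ROI per plane, equal-sized disks placed
  fully inside a single zone, in opposite zones of each other.

Malignant tissue differs from its host zone by configurable offsets (higher
v, E, kappa, alpha, PI; shorter mu and hence WIT); per-patient random
multipliers and per-patient effect-size multipliers (independent across
parameters) emulate biological and tumor heterogeneity.  Setting
``malignant_effect_scale = 0`` yields a null cohort in which ROI labels are
uninformative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from mpus.data_model import (
    LABEL_BENIGN,
    LABEL_MALIGNANT,
    ZONE_PZ,
    ZONE_TZ,
    DcePlane,
    PlaneBundle,
    RunConfig,
    radius_mm_to_px,
    save_plane_bundle,
)
from mpus.motion_compensation import RigidTransform, warp_rigid
from mpus.tic_features import ldrw_model

KINETIC_PARAMS = ("mu", "kappa", "alpha", "v", "D", "E")


@dataclass
class TissueParams:
    """Mean kinetic/stiffness parameters of one tissue class."""

    mu: float      # mean transit time, s
    kappa: float   # dispersion-related, 1/s
    alpha: float   # area under TIC, a.u.*s
    v: float       # contrast velocity, mm/s
    D: float       # dispersion, mm^2/s
    E: float       # Young's modulus, kPa


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort."""

    n_patients: int = 12
    planes_per_patient: int = 3
    grid_shape: tuple[int, int] = (144, 192)     # (rows, cols)
    pixel_spacing_mm: float = 0.167
    frame_rate_hz: float = 5.0
    duration_s: float = 120.0

    # Tissue parameters: TZ stiffer and better perfused than benign PZ;
    # lesions stiffer, faster (higher v, shorter mu/WIT) and more enhancing
    # than their host zone.  Effect sizes are deliberately moderate relative
    # to the between-patient variability below, so that any single parameter
    # discriminates only partially (the regime in which a multiparametric
    # combination is worthwhile at all).
    pz: TissueParams = field(default_factory=lambda: TissueParams(
        mu=25.0, kappa=0.5, alpha=60.0, v=0.8, D=0.20, E=25.0))
    tz: TissueParams = field(default_factory=lambda: TissueParams(
        mu=22.0, kappa=0.6, alpha=80.0, v=1.0, D=0.25, E=45.0))
    lesion: TissueParams = field(default_factory=lambda: TissueParams(
        mu=18.5, kappa=0.8, alpha=90.0, v=1.4, D=0.28, E=55.0))

    malignant_effect_scale: float = 1.0   # 0 => null cohort
    patient_sd_rel: float = 0.10          # lognormal per-patient multiplier SD
    effect_sd_rel: float = 0.5            # lognormal per-patient effect-size SD
    spatial_sd_rel: float = 0.06          # within-plane smooth field SD
    spatial_smooth_mm: float = 1.5

    t0_base_s: float = 14.0
    t0_patient_sd_s: float = 1.0
    noise_level: float = 0.05             # temporal noise rel. to local peak
    static_echo_rel: float = 0.15         # static tissue signal rel. to peak

    swe_patient_sd_kpa: float = 8.0
    swe_smooth_noise_kpa: float = 3.0
    swe_pixel_noise_kpa: float = 1.5

    bmode_mean: float = 110.0
    bmode_gain_sd_rel: float = 0.10       # per-patient gain variability
    speckle_shape: float = 6.0            # gamma-speckle shape parameter
    calc_density_per_cm2: float = 0.15
    calc_contrast: float = 4.0
    calc_stiffening_kpa: float = 30.0

    motion_amp_mm: float = 1.0
    motion_amp_deg: float = 1.0
    motion_period_s: float = 45.0

    lesions_per_plane: int = 1
    lesion_radius_mm: tuple[float, float] = (1.7, 2.2)
    roi_radius_mm: float = 0.8
    gamma_variate_mode: bool = False      # kinetic-model mis-specification

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """Reduced-scale profile used for bundled demonstrations and the
        end-to-end validation runs: one plane per patient on a 72x96 grid,
        2 Hz over 96 s.  Tissue parameters and effect sizes are unchanged."""
        base = dict(grid_shape=(72, 96), planes_per_patient=1,
                    frame_rate_hz=2.0, duration_s=96.0)
        base.update(overrides)
        return cls(**base)

    def null(self) -> "SimConfig":
        """Copy of this configuration with malignant offsets switched off."""
        return dataclasses.replace(self, malignant_effect_scale=0.0)


@dataclass
class PlaneTruth:
    tissue: np.ndarray          # 0 outside, 1 benign PZ, 2 benign TZ, 3 lesion
    lesion_mask: np.ndarray
    true_maps: dict[str, np.ndarray]
    motion: list[RigidTransform]


@dataclass
class SimTruth:
    patient_id: str
    planes: list[PlaneTruth]


def _ellipse_mask(shape, center, semi) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius_px) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px ** 2


def _smooth_field(rng, shape, smooth_px, sd) -> np.ndarray:
    """exp of a smoothed, unit-variance Gaussian field scaled to ``sd``."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_px)
    s = f.std()
    if s > 0:
        f = f / s
    return np.exp(sd * f)


def _place_in_zone(rng, zone_mask: np.ndarray, margin_px: int) -> tuple[int, int]:
    """A random pixel at least ``margin_px`` inside the zone (falls back to
    the deepest pixel when the zone is too thin)."""
    dist = ndimage.distance_transform_edt(zone_mask)
    eligible = np.argwhere(dist >= margin_px)
    if len(eligible) == 0:
        eligible = np.argwhere(dist == dist.max())
    r, c = eligible[rng.integers(len(eligible))]
    return int(r), int(c)


def _gamma_variate(t, alpha, kappa, mu, t0):
    """Gamma-variate bolus with matched mean transit time and variance."""
    from scipy import stats as _st

    tau = np.clip(t - t0, 0.0, None)
    k = mu * kappa
    return alpha * _st.gamma.pdf(tau, a=k, scale=1.0 / kappa)


def simulate_patient(cfg: SimConfig, patient_seed: int, patient_id: str = "P00",
                     lesion_zone_start: int = ZONE_PZ,
                     ) -> tuple[list[PlaneBundle], SimTruth]:
    """Simulate all planes of one patient.  Deterministic given
    (cfg, patient_seed); the lesion of plane ``p`` sits in
    ``lesion_zone_start`` for even ``p`` and in the other zone otherwise."""
    rng = np.random.default_rng(patient_seed)
    rows, cols = cfg.grid_shape
    sp = cfg.pixel_spacing_mm
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n_frames) / cfg.frame_rate_hz
    smooth_px = max(cfg.spatial_smooth_mm / sp, 1.0)
    scale = cfg.malignant_effect_scale

    # patient-level multipliers: one per kinetic parameter, independent
    pmul = {k: float(np.exp(rng.normal(0.0, cfg.patient_sd_rel)))
            for k in KINETIC_PARAMS}
    emul = {k: float(np.exp(rng.normal(0.0, cfg.effect_sd_rel)))
            for k in KINETIC_PARAMS}
    e_patient_off = float(rng.normal(0.0, cfg.swe_patient_sd_kpa))
    t0_off = float(rng.normal(0.0, cfg.t0_patient_sd_s))
    bmode_gain = float(np.exp(rng.normal(0.0, cfg.bmode_gain_sd_rel)))

    plane_names = ("apex", "mid", "base")
    bundles, truths = [], []
    for p in range(cfg.planes_per_patient):
        plane_id = plane_names[p] if cfg.planes_per_patient <= 3 else f"plane{p}"
        center = (rows / 2 + rng.uniform(-2, 2), cols / 2 + rng.uniform(-2, 2))
        semi = (0.36 * rows * rng.uniform(0.95, 1.05),
                0.38 * cols * rng.uniform(0.95, 1.05))
        prostate = _ellipse_mask((rows, cols), center, semi)
        tz_center = (center[0] - 0.10 * semi[0], center[1])
        tz = _ellipse_mask((rows, cols), tz_center, (0.5 * semi[0], 0.5 * semi[1]))
        tz &= prostate
        zone = np.zeros((rows, cols), np.uint8)
        zone[prostate] = ZONE_PZ
        zone[tz] = ZONE_TZ

        roi_r = radius_mm_to_px(cfg.roi_radius_mm, sp)
        lesion_zone = lesion_zone_start if p % 2 == 0 else (
            ZONE_TZ if lesion_zone_start == ZONE_PZ else ZONE_PZ)
        benign_zone = ZONE_TZ if lesion_zone == ZONE_PZ else ZONE_PZ

        # ROI placement is deliberately symmetric between the classes: both
        # centers are drawn with the same margin rule inside their zone, so
        # under a null cohort the labels carry no positional information
        lesion_mask = np.zeros((rows, cols), bool)
        roi = np.zeros((rows, cols), np.uint8)
        lesion_centers = []
        for _ in range(cfg.lesions_per_plane):
            lc = _place_in_zone(rng, zone == lesion_zone, roi_r + 1)
            lr = radius_mm_to_px(rng.uniform(*cfg.lesion_radius_mm), sp)
            lesion_mask |= _disk_mask((rows, cols), lc, lr) & prostate
            lesion_centers.append((lc, lr))
            if not roi.any():
                roi[_disk_mask((rows, cols), lc, roi_r)] = LABEL_MALIGNANT
        for _ in range(20):
            bc = _place_in_zone(rng, zone == benign_zone, roi_r + 1)
            if all(np.hypot(bc[0] - lc[0], bc[1] - lc[1]) > lr + roi_r + 1
                   for lc, lr in lesion_centers):
                break
        roi[_disk_mask((rows, cols), bc, roi_r)] = LABEL_BENIGN

        tissue = np.zeros((rows, cols), np.uint8)
        tissue[zone == ZONE_PZ] = 1
        tissue[zone == ZONE_TZ] = 2
        tissue[lesion_mask] = 3

        # parameter fields: zone base + scaled lesion offset, patient and
        # spatial modulation
        zone_base = {ZONE_PZ: cfg.pz, ZONE_TZ: cfg.tz}
        true_maps: dict[str, np.ndarray] = {}
        for k in KINETIC_PARAMS:
            fld = np.full((rows, cols), np.nan)
            for z in (ZONE_PZ, ZONE_TZ):
                m = zone == z
                base_val = getattr(zone_base[z], k)
                les_val = base_val + scale * emul[k] * (getattr(cfg.lesion, k) - base_val)
                vals = np.where(lesion_mask[m], les_val, base_val)
                fld[m] = vals
            if k == "E":
                fld = fld + e_patient_off
            else:
                fld = fld * pmul[k]
            fld *= _smooth_field(rng, (rows, cols), smooth_px, cfg.spatial_sd_rel)
            true_maps[k] = fld

        # bolus arrival propagates from an inflow origin placed randomly in
        # the TZ (the urethral/neurovascular inflow is not at a fixed
        # landmark), at the local contrast velocity
        origin = _place_in_zone(rng, zone == ZONE_TZ, 3)
        rr, cc = np.mgrid[0:rows, 0:cols]
        dist_mm = np.hypot(rr - origin[0], cc - origin[1]) * sp
        v_fld = np.where(prostate, true_maps["v"], 1.0)
        t0_map = cfg.t0_base_s + t0_off + dist_mm / np.clip(v_fld, 0.1, None)
        true_maps["t0"] = np.where(prostate, t0_map, np.nan)

        # synthesize the loop
        pr, pc = np.nonzero(prostate)
        curve_fn = _gamma_variate if cfg.gamma_variate_mode else ldrw_model
        Y = np.zeros((n_frames, len(pr)))
        # vectorized closed-form evaluation over all prostate pixels
        al = true_maps["alpha"][pr, pc]
        ka = true_maps["kappa"][pr, pc]
        mu = true_maps["mu"][pr, pc]
        tz0 = t0_map[pr, pc]
        if cfg.gamma_variate_mode:
            for j in range(len(pr)):
                Y[:, j] = curve_fn(t, al[j], ka[j], mu[j], tz0[j])
        else:
            tau = t[:, None] - tz0[None, :]
            pos = tau > 1e-9
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                body = (al * np.sqrt(ka / (2 * np.pi * np.where(pos, tau, 1.0)))
                        * np.exp(-ka * (tau - mu) ** 2 / (2 * np.where(pos, tau, 1.0))))
            Y = np.where(pos, body, 0.0)
        peak = Y.max(axis=0)
        mean_peak = float(peak.mean()) if len(peak) else 1.0

        frames = np.zeros((n_frames, rows, cols))
        frames[:, pr, pc] = Y
        static = cfg.static_echo_rel * mean_peak * _smooth_field(
            rng, (rows, cols), 1.0, 0.5)
        frames += static[None]
        if cfg.noise_level > 0:
            sigma = cfg.noise_level * np.maximum(
                frames.max(axis=0), 0.2 * mean_peak)
            frames += rng.standard_normal(frames.shape) * sigma[None]
        frames = np.clip(frames, 0.0, None)

        # rigid drift, zero at the 30-s reference time
        motion: list[RigidTransform] = []
        if cfg.motion_amp_mm > 0 or cfg.motion_amp_deg > 0:
            ph = rng.uniform(0, 2 * np.pi, size=2)
            arg = 2 * np.pi * (t - 30.0) / cfg.motion_period_s
            txs = cfg.motion_amp_mm * np.sin(arg)
            tys = cfg.motion_amp_mm * np.sin(arg + ph[0])
            ths = cfg.motion_amp_deg * np.sin(arg + ph[1])
            for i in range(n_frames):
                m = RigidTransform((float(txs[i]), float(tys[i])), float(ths[i]), i)
                motion.append(m)
                if not m.is_identity(1e-9):
                    frames[i] = warp_rigid(frames[i], m, (sp, sp))
            frames = np.clip(frames, 0.0, None)

        # SWE map
        swe = np.where(prostate, true_maps["E"], 15.0)
        swe = swe + ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), smooth_px) * cfg.swe_smooth_noise_kpa
        swe = swe + rng.standard_normal((rows, cols)) * cfg.swe_pixel_noise_kpa

        # B-mode with speckle and calcifications
        echo = np.full((rows, cols), 0.6 * cfg.bmode_mean)
        echo[zone == ZONE_PZ] = cfg.bmode_mean
        echo[zone == ZONE_TZ] = 0.88 * cfg.bmode_mean
        # lesions subtly hypoechoic relative to their host zone
        echo[lesion_mask] += scale * (0.84 * cfg.bmode_mean - echo[lesion_mask])
        echo *= bmode_gain
        calc = np.zeros((rows, cols), bool)
        area_cm2 = prostate.sum() * (sp / 10.0) ** 2
        for _ in range(rng.poisson(cfg.calc_density_per_cm2 * area_cm2)):
            ccen = _place_in_zone(rng, prostate, 3)
            cr = radius_mm_to_px(rng.uniform(0.5, 1.9), sp)
            calc |= _disk_mask((rows, cols), ccen, cr) & prostate
        echo[calc] *= cfg.calc_contrast
        speck = rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape, (rows, cols))
        bmode = echo * speck
        swe = np.clip(swe + np.where(calc, cfg.calc_stiffening_kpa, 0.0), 2.0, None)
        true_maps["E"] = np.where(prostate, np.clip(true_maps["E"], 2.0, None), np.nan)

        dce = DcePlane(frames=frames.astype(np.float32), timestamps=t,
                       pixel_spacing=(sp, sp), patient_id=patient_id,
                       plane_id=plane_id)
        bundles.append(PlaneBundle(dce=dce, bmode=bmode, swe=swe,
                                   prostate_mask=prostate, zone_mask=zone,
                                   calcification_mask=calc, roi_labels=roi))
        for k in KINETIC_PARAMS:
            true_maps[k] = np.where(prostate, true_maps[k], np.nan)
        truths.append(PlaneTruth(tissue=tissue, lesion_mask=lesion_mask,
                                 true_maps=true_maps, motion=motion))
    return bundles, SimTruth(patient_id=patient_id, planes=truths)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def audit_balance(bundles: list[PlaneBundle]) -> dict:
    """ROI pixel bookkeeping: benign vs malignant and PZ vs TZ provenance."""
    nb = nm = 0
    zone_px = {ZONE_PZ: 0, ZONE_TZ: 0}
    for b in bundles:
        nb += int((b.roi_labels == LABEL_BENIGN).sum())
        nm += int((b.roi_labels == LABEL_MALIGNANT).sum())
        labeled = b.roi_labels != 0
        for z in (ZONE_PZ, ZONE_TZ):
            zone_px[z] += int((labeled & (b.zone_mask == z)).sum())
    def _imb(a, b2):
        return abs(a - b2) / max(a, b2, 1)
    return {"benign_px": nb, "malignant_px": nm,
            "pz_px": zone_px[ZONE_PZ], "tz_px": zone_px[ZONE_TZ],
            "class_imbalance": _imb(nb, nm),
            "zone_imbalance": _imb(zone_px[ZONE_PZ], zone_px[ZONE_TZ])}


def simulate_cohort_bundles(cfg: SimConfig, seed: int
                            ) -> tuple[list[PlaneBundle], list[SimTruth]]:
    """Simulate a full cohort in memory; lesion zones alternate across
    patients so ROI class and zone provenance stay balanced (within 10 %)."""
    if cfg.n_patients < 8:
        raise ValueError("a cohort needs at least 8 patients")
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, cfg.n_patients)
    bundles: list[PlaneBundle] = []
    truths: list[SimTruth] = []
    for i in range(cfg.n_patients):
        start = ZONE_PZ if i % 2 == 0 else ZONE_TZ
        pb, tr = simulate_patient(cfg, int(seeds[i]), patient_id=f"P{i:02d}",
                                  lesion_zone_start=start)
        bundles.extend(pb)
        truths.append(tr)
    bal = audit_balance(bundles)
    if bal["class_imbalance"] > 0.10 or bal["zone_imbalance"] > 0.10:
        raise AssertionError(f"ROI balancing invariant violated: {bal}")
    return bundles, truths


def simulate_cohort(cfg: SimConfig, seed: int, out_dir: str | Path) -> Path:
    """Simulate a cohort and write it as an on-disk dataset loadable by
    :func:`mpus.data_model.load_plane_bundle`, with a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles, _ = simulate_cohort_bundles(cfg, seed)
    manifest: dict = {"seed": int(seed), "planes": []}
    for b in bundles:
        rel = Path(b.patient_id) / b.plane_id
        save_plane_bundle(b, out_dir / rel)
        manifest["planes"].append({"patient_id": b.patient_id,
                                   "plane_id": b.plane_id, "dir": str(rel)})
    cfg_d = dataclasses.asdict(cfg)
    manifest["sim_config"] = yaml.safe_load(yaml.safe_dump(cfg_d))
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out_dir
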