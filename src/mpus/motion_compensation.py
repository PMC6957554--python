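"""Rigid motion compensation of DCE-US cine loops.

The prostate position during wash-in (the frame nearest 30 s) serves as the
reference.  Every 5th frame is rigidly registered to it — translation and
in-plane rotation about the image center, found by maximizing normalized
cross-correlation over a coarse-to-fine search — and the transforms of the
intermediate frames are obtained by componentwise linear interpolation of
``(tx, ty, theta)`` between anchors.

Transform convention: the stored translation/rotation describe the in-plane
displacement of the frame content relative to the reference, so warping a
frame *by* its transform re-aligns it with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from mpus.data_model import DcePlane, RunConfig


@dataclass
class RigidTransform:
    """In-plane rigid transform: translation in mm (row, col) and rotation
    in degrees about the image center."""

    translation: tuple[float, float]
    rotation: float
    frame_index: int = -1
    anchor: bool = False
    warning: str = ""

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.translation[0]) <= tol
            and abs(self.translation[1]) <= tol
            and abs(self.rotation) <= tol
        )

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (isotropic pixel spacing assumed):
        warping by a transform and then by its inverse is the identity."""
        th = np.deg2rad(self.rotation)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        s = -rot @ np.asarray(self.translation)
        return RigidTransform((float(s[0]), float(s[1])), -self.rotation,
                              self.frame_index, self.anchor, self.warning)


@dataclass
class CompensationResult:
    plane: DcePlane
    transforms: pd.DataFrame  # frame, tx_mm, ty_mm, rot_deg, anchor_flag


def estimate_reference_frame(dce: DcePlane, config: RunConfig | None = None) -> int:
    """Index of the frame whose timestamp is nearest the wash-in reference
    time (30 s by default); ties resolve toward the earlier frame."""
    t_ref = (config or RunConfig()).reference_time_s
    t = dce.timestamps
    if t[-1] < t_ref:
        raise ValueError(
            f"loop spans only {t[-1]:.1f} s; a {t_ref:.0f}-s reference frame requires "
            "a longer recording"
        )
    return int(np.argmin(np.abs(t - t_ref)))


def _rotate_about_center(img: np.ndarray, theta_deg: float, order: int = 1) -> np.ndarray:
    if theta_deg == 0.0:
        return img
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    center = (np.asarray(img.shape) - 1) / 2.0
    offset = center - rot @ center
    return ndimage.affine_transform(img, rot, offset=offset, order=order, mode="nearest")


def warp_rigid(img: np.ndarray, transform: RigidTransform,
               pixel_spacing: tuple[float, float]) -> np.ndarray:
    """Warp a frame by a rigid transform (aligns the frame to the reference)."""
    if transform.is_identity():
        return img.copy()
    s = np.array([transform.translation[0] / pixel_spacing[0],
                  transform.translation[1] / pixel_spacing[1]])
    th = np.deg2rad(transform.rotation)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    center = (np.asarray(img.shape) - 1) / 2.0
    # output(y) = img(R @ (y - c + s) + c)
    offset = center - rot @ (center - s)
    return ndimage.affine_transform(img.astype(float), rot, offset=offset,
                                    order=1, mode="nearest")


def _xcorr_peak(moving: np.ndarray, reference: np.ndarray,
                max_shift_px: int) -> tuple[float, float, float]:
    """Best (drow, dcol) content shift of ``moving`` vs ``reference`` within
    the allowed lag window, with parabolic subpixel refinement.

    Returns (drow, dcol, score); score is the normalized correlation at the
    integer peak.
    """
    a = moving - moving.mean()
    b = reference - reference.mean()
    fa, fb = np.fft.rfft2(a), np.fft.rfft2(b)
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    corr = np.fft.fftshift(corr)
    c0 = np.array(a.shape) // 2
    m = int(max_shift_px)
    win = corr[c0[0] - m:c0[0] + m + 1, c0[1] - m:c0[1] + m + 1]
    ij = np.unravel_index(np.argmax(win), win.shape)
    peak = win[ij]
    norm = np.sqrt((a * a).sum() * (b * b).sum())
    score = float(peak / norm) if norm > 0 else 0.0

    def _sub(vals: np.ndarray, i: int) -> float:
        if 0 < i < len(vals) - 1:
            denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
            if denom < 0:
                return float(np.clip(0.5 * (vals[i - 1] - vals[i + 1]) / denom, -0.5, 0.5))
        return 0.0

    dr = ij[0] - m + _sub(win[:, ij[1]], ij[0])
    dc = ij[1] - m + _sub(win[ij[0], :], ij[1])
    return float(dr), float(dc), score


def estimate_rigid(moving: np.ndarray, reference: np.ndarray,
                   pixel_spacing: tuple[float, float],
                   config: RunConfig | None = None,
                   frame_index: int = -1) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``reference``.

    Coarse-to-fine: a 1-degree rotation grid over the allowed range with an
    FFT translation search at each rotation, then a 0.1-degree refinement
    around the best rotation; translations are refined to subpixel by
    parabolic interpolation of the correlation peak.
    """
    cfg = config or RunConfig()
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference frames must share one shape")
    if moving.std() == 0 or reference.std() == 0:
        return RigidTransform((0.0, 0.0), 0.0, frame_index,
                              warning="flat frame; identity assumed")

    spacing = float(np.mean(pixel_spacing))
    max_shift_px = max(1, int(np.ceil(cfg.moco_max_shift_mm / spacing)))
    max_rot = cfg.moco_max_rot_deg

    def _best_at(theta: float) -> tuple[float, float, float, float]:
        rotated = _rotate_about_center(moving, theta)
        dr, dc, score = _xcorr_peak(rotated, reference, max_shift_px)
        return dr, dc, score, theta

    coarse = [_best_at(th) for th in np.arange(-max_rot, max_rot + 0.5, 1.0)]
    best = max(coarse, key=lambda t: t[2])
    fine_grid = np.arange(best[3] - 1.0, best[3] + 1.0 + 1e-9, 0.1)
    fine = [_best_at(th) for th in fine_grid]
    scores = np.array([f[2] for f in fine])
    k = int(np.argmax(scores))
    theta = fine[k][3]
    if 0 < k < len(fine) - 1:
        denom = scores[k - 1] - 2 * scores[k] + scores[k + 1]
        if denom < 0:
            theta += 0.1 * float(np.clip(0.5 * (scores[k - 1] - scores[k + 1]) / denom,
                                         -0.5, 0.5))
        dr, dc, score, _ = _best_at(theta)
    else:
        dr, dc, score, _ = fine[k]
    # snap sub-milli-pixel estimates to the exact identity so static loops
    # pass through untouched
    if abs(dr) < 1e-3 and abs(dc) < 1e-3 and abs(theta) < 1e-3:
        dr = dc = theta = 0.0
    return RigidTransform(
        translation=(dr * pixel_spacing[0], dc * pixel_spacing[1]),
        rotation=float(theta),
        frame_index=frame_index,
        anchor=True,
    )


def _interpolate_transforms(anchors: list[RigidTransform], n_frames: int
                            ) -> list[RigidTransform]:
    """Componentwise linear interpolation of (tx, ty, theta) between anchors;
    frames beyond the first/last anchor reuse the nearest anchor."""
    idx = np.array([a.frame_index for a in anchors])
    tx = np.array([a.translation[0] for a in anchors])
    ty = np.array([a.translation[1] for a in anchors])
    th = np.array([a.rotation for a in anchors])
    frames = np.arange(n_frames)
    out = []
    anchor_set = set(idx.tolist())
    for f, x, y, r in zip(frames,
                          np.interp(frames, idx, tx),
                          np.interp(frames, idx, ty),
                          np.interp(frames, idx, th)):
        out.append(RigidTransform((float(x), float(y)), float(r), int(f),
                                  anchor=int(f) in anchor_set))
    return out


def compensate(dce: DcePlane, config: RunConfig | None = None) -> CompensationResult:
    """Motion-compensate a DCE-US loop against its 30-s reference frame.

    Transforms are estimated at every ``moco_stride``-th frame (anchored at
    the reference index, extending in both directions) and interpolated for
    the frames in between; each frame is then warped by its transform.
    """
    cfg = config or RunConfig()
    if dce.n_frames < 6:
        raise ValueError("motion compensation requires at least 6 frames")
    ref_idx = estimate_reference_frame(dce, cfg)
    reference = dce.frames[ref_idx].astype(float)

    stride = max(1, int(cfg.moco_stride))
    anchor_idx = sorted(set(
        list(range(ref_idx, -1, -stride)) + list(range(ref_idx, dce.n_frames, stride))
    ))
    anchors = []
    for i in anchor_idx:
        if i == ref_idx:
            anchors.append(RigidTransform((0.0, 0.0), 0.0, i, anchor=True))
        else:
            anchors.append(estimate_rigid(dce.frames[i].astype(float), reference,
                                          dce.pixel_spacing, cfg, frame_index=i))
    transforms = _interpolate_transforms(anchors, dce.n_frames)

    out = np.empty_like(dce.frames, dtype=np.float32)
    for i, tr in enumerate(transforms):
        frame = dce.frames[i].astype(float)
        out[i] = frame if tr.is_identity() else warp_rigid(frame, tr, dce.pixel_spacing)
    plane = DcePlane(frames=out, timestamps=dce.timestamps.copy(),
                     pixel_spacing=dce.pixel_spacing,
                     patient_id=dce.patient_id, plane_id=dce.plane_id)
    table = pd.DataFrame({
        "frame": [t.frame_index for t in transforms],
        "tx_mm": [t.translation[0] for t in transforms],
        "ty_mm": [t.translation[1] for t in transforms],
        "rot_deg": [t.rotation for t in transforms],
        "anchor_flag": [t.anchor for t in transforms],
    })
    return CompensationResult(plane=plane, transforms=table)
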