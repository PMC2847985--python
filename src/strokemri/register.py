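"""Brain extraction, rigid 6-DOF registration and atlas-space resampling.

Registration maximizes a masked normalized cross-correlation over the
six-parameter rigid pose with a two-level multi-resolution, derivative-free
(Powell) search — an intra-modality replacement for the step-wise affine
alignment of the emulated study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .geometry import AcquisitionGeometry
from .maps import QuantitativeMap
from .phantom import AtlasTemplate
from .transforms import RigidTransform, resample, resample_validity

__all__ = [
    "BrainMask",
    "RegistrationOptions",
    "RegistrationResult",
    "extract_brain",
    "register_rigid",
    "to_atlas",
]


@dataclass
class BrainMask:
    mask: np.ndarray
    source: str  # "ground_truth" | "threshold_morphology"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("brain mask is empty")


def extract_brain(volume: np.ndarray, mode: str = "automatic",
                  ground_truth_mask: Optional[np.ndarray] = None) -> BrainMask:
    """Strip scalp/skull (emulating manual extraction).

    ``ground_truth`` mode passes the phantom mask through; ``automatic`` mode
    applies Otsu thresholding, keeps the largest connected component and
    closes small gaps morphologically.
    """
    if mode == "ground_truth":
        if ground_truth_mask is None:
            raise ValueError("ground_truth mode requires a phantom mask")
        return BrainMask(np.asarray(ground_truth_mask, dtype=bool), "ground_truth")
    if mode != "automatic":
        raise ValueError(f"unknown extraction mode {mode!r}")

    vol = np.asarray(volume, dtype=float)
    if not np.any(vol > 0) or vol.max() == vol.min():
        raise ValueError("cannot extract brain from a constant/empty volume")
    thr = threshold_otsu(vol)
    fg = vol > thr
    if not fg.any():
        raise ValueError("automatic brain extraction produced an empty mask")
    labels = cc_label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    fg = labels == int(np.argmax(counts))
    structure = ndimage.generate_binary_structure(3, 1)
    # pad so closing does not erode anatomy touching the volume edge
    padded = np.pad(fg, 3)
    padded = ndimage.binary_closing(padded, structure=structure, iterations=2)
    padded = ndimage.binary_fill_holes(padded)
    fg = padded[3:-3, 3:-3, 3:-3]
    return BrainMask(fg, "threshold_morphology")


@dataclass(frozen=True)
class RegistrationOptions:
    coarse_factor: int = 2
    smooth_sigma_vox: Tuple[float, float, float] = (2.0, 2.0, 1.0)
    fine_smooth_sigma_vox: Tuple[float, float, float] = (2.0, 2.0, 1.2)
    multistart_rot_deg: Tuple[float, ...] = (2.0, 4.0)
    multistart_trans_vox: Tuple[float, ...] = (1.0, 2.0)
    n_refine_starts: int = 4
    coarse_maxiter: int = 30
    fine_maxiter: int = 120
    min_overlap_voxels: int = 64
    # correlate over the eroded brain core: rim voxels carry interpolation
    # blur of the tissue/background edge, not pose information
    erode_fixed_mask_vox: Tuple[int, int, int] = (2, 2, 1)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric_initial: float
    metric_final: float
    n_evaluations: int
    converged: bool


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray, min_overlap: int) -> float:
    if mask.sum() < min_overlap:
        return -1.0
    x = a[mask]
    y = b[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return -1.0
    return float((x * y).sum() / denom)


def _downsample(volume: np.ndarray, geometry: AcquisitionGeometry, factor: int,
                sigma: Tuple[float, float, float], order: int) -> Tuple[np.ndarray, AcquisitionGeometry]:
    if factor == 1:
        return volume, geometry
    if order > 0:
        sm = ndimage.gaussian_filter(volume.astype(float), sigma)
    else:
        sm = volume.astype(float)
    out = sm[::factor, ::factor, :]
    geo = geometry.with_matrix(out.shape[0], out.shape[1], out.shape[2])
    return out, geo


class _Metric:
    """Negative masked NCC of the moving image resampled at a candidate pose."""

    def __init__(self, moving, fixed, moving_mask, fixed_mask,
                 moving_geo, fixed_geo, center, min_overlap):
        self.moving = moving
        self.fixed = fixed
        self.moving_mask = moving_mask.astype(np.uint8)
        self.fixed_mask = fixed_mask
        self.moving_geo = moving_geo
        self.fixed_geo = fixed_geo
        self.center = center
        self.min_overlap = min_overlap
        self.n_eval = 0

    def transform(self, params: np.ndarray) -> RigidTransform:
        return RigidTransform(tuple(params[:3]), tuple(params[3:6]), self.center)

    def __call__(self, params: np.ndarray) -> float:
        self.n_eval += 1
        t = self.transform(params)
        warped = resample(self.moving, t, self.moving_geo, self.fixed_geo, "trilinear")
        wmask = resample(self.moving_mask, t, self.moving_geo, self.fixed_geo,
                         "nearest") > 0
        overlap = wmask & self.fixed_mask
        return -_masked_ncc(warped, self.fixed, overlap, self.min_overlap)


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    moving_mask: Optional[np.ndarray] = None,
    fixed_mask: Optional[np.ndarray] = None,
    moving_geometry: Optional[AcquisitionGeometry] = None,
    fixed_geometry: Optional[AcquisitionGeometry] = None,
    opts: RegistrationOptions = RegistrationOptions(),
    initial: Optional[RigidTransform] = None,
) -> RegistrationResult:
    """Estimate the rigid moving-to-fixed world transform.

    Two-level coarse-to-fine Powell search over (3 rotations deg,
    3 translations mm) maximizing masked NCC; the coarse level screens a
    small multi-start set (+/- 2 deg / +/- 1 voxel single-axis perturbations)
    and Powell-refines the best candidates.
    """
    if moving_geometry is None or fixed_geometry is None:
        raise ValueError("moving_geometry and fixed_geometry are required")
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving_mask is None:
        moving_mask = moving > 0
    if fixed_mask is None:
        fixed_mask = fixed > 0
    moving_mask = np.asarray(moving_mask, dtype=bool)
    fixed_mask = np.asarray(fixed_mask, dtype=bool)
    if not moving_mask.any() or not fixed_mask.any():
        raise ValueError("registration masks must be nonempty")
    if np.ptp(moving[moving_mask]) == 0 or np.ptp(fixed[fixed_mask]) == 0:
        raise ValueError("cannot register constant images")

    center = fixed_geometry.center_mm
    p0 = np.zeros(6)
    if initial is not None:
        p0 = np.array(list(initial.rotations_deg) + list(initial.translations_mm))

    ex, ey, ez = opts.erode_fixed_mask_vox
    if max(ex, ey, ez) > 0:
        core = ndimage.binary_erosion(
            fixed_mask, structure=np.ones((2 * ex + 1, 2 * ey + 1, 2 * ez + 1), dtype=bool))
        if core.sum() >= opts.min_overlap_voxels:
            fixed_mask = core

    # ---- coarse level ----
    factor = opts.coarse_factor
    mv_c, mv_geo_c = _downsample(moving, moving_geometry, factor, opts.smooth_sigma_vox, 1)
    fx_c, fx_geo_c = _downsample(fixed, fixed_geometry, factor, opts.smooth_sigma_vox, 1)
    mvm_c, _ = _downsample(moving_mask.astype(float), moving_geometry, factor,
                           opts.smooth_sigma_vox, 1)
    fxm_c, _ = _downsample(fixed_mask.astype(float), fixed_geometry, factor,
                           opts.smooth_sigma_vox, 1)
    metric_c = _Metric(mv_c, fx_c, mvm_c > 0.5, fxm_c > 0.5, mv_geo_c, fx_geo_c,
                       center, max(opts.min_overlap_voxels // (factor * factor), 16))

    dvox = min(fixed_geometry.spacing_mm)
    starts = [p0.copy()]
    for axis in range(3):
        for sgn in (-1.0, 1.0):
            for rot_amp in opts.multistart_rot_deg:
                s = p0.copy()
                s[axis] += sgn * rot_amp
                starts.append(s)
            for trans_amp in opts.multistart_trans_vox:
                s = p0.copy()
                s[3 + axis] += sgn * trans_amp * dvox
                starts.append(s)
    scored = sorted(starts, key=metric_c)
    best = None
    for s in scored[: opts.n_refine_starts]:
        res = optimize.minimize(metric_c, s, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-6,
                                         "maxiter": opts.coarse_maxiter})
        if best is None or res.fun < best.fun:
            best = res

    # ---- fine level ----
    # Both sides are smoothed identically: this equalizes the interpolation
    # blur the warped moving image acquires and stops sharp tissue/background
    # edges from dominating the correlation.
    mv_f = ndimage.gaussian_filter(moving, opts.fine_smooth_sigma_vox)
    fx_f = ndimage.gaussian_filter(fixed, opts.fine_smooth_sigma_vox)
    metric_f = _Metric(mv_f, fx_f, moving_mask, fixed_mask,
                       moving_geometry, fixed_geometry, center, opts.min_overlap_voxels)
    initial_metric = -metric_f(p0)
    res = optimize.minimize(metric_f, best.x, method="Powell",
                            options={"xtol": 1e-6, "ftol": 1e-12,
                                     "maxiter": opts.fine_maxiter})
    final_metric = -res.fun
    transform = metric_f.transform(res.x)
    converged = bool(res.success) and final_metric > -1.0
    if final_metric < initial_metric:
        # never return a pose worse than the starting one
        transform = metric_f.transform(p0)
        final_metric = initial_metric
    if not converged:
        raise RuntimeError(
            f"rigid registration did not converge (final NCC = {final_metric:.4f})"
        )
    return RegistrationResult(
        transform=transform,
        metric_initial=float(initial_metric),
        metric_final=float(final_metric),
        n_evaluations=metric_c.n_eval + metric_f.n_eval,
        converged=converged,
    )


def to_atlas(
    subject_maps: Dict[str, QuantitativeMap],
    transform: RigidTransform,
    template: AtlasTemplate,
    subject_geometry: Optional[AcquisitionGeometry] = None,
    masks: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[Dict[str, QuantitativeMap], Dict[str, np.ndarray]]:
    """Resample subject-space maps and masks onto the template grid.

    Map values use trilinear interpolation; validity masks and label/binary
    masks use nearest neighbour. Out-of-field voxels are removed from every
    validity mask so that atlas-edge fill values never enter ROI statistics.
    """
    if subject_geometry is None:
        subject_geometry = template.geometry
    tgt = template.geometry
    infield = resample_validity(transform, subject_geometry, tgt)
    out_maps: Dict[str, QuantitativeMap] = {}
    for name, qmap in subject_maps.items():
        if qmap.shape != subject_geometry.shape:
            raise ValueError(f"map {name!r} is not on the subject grid")
        values = resample(np.nan_to_num(qmap.values, nan=0.0), transform,
                          subject_geometry, tgt, "trilinear")
        validity = resample(qmap.validity_mask.astype(np.uint8), transform,
                            subject_geometry, tgt, "nearest") > 0
        validity &= infield
        values = np.where(validity, values, np.nan)
        out_maps[name] = QuantitativeMap(values, qmap.units, validity,
                                         diagnostics=dict(qmap.diagnostics))
        if out_maps[name].shape != tgt.shape:
            raise ValueError("grid mismatch after resampling")
    out_masks: Dict[str, np.ndarray] = {}
    for name, m in (masks or {}).items():
        res = resample(np.asarray(m, dtype=np.uint8), transform,
                       subject_geometry, tgt, "nearest") > 0
        out_masks[name] = res & infield
    return out_maps, out_masks
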