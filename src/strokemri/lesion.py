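"""Infarct segmentation, CSF removal and volumetry.

Binary infarct masks come either from a fixed T2 threshold (34 ms by
default, strict inequality) applied to quantitative T2 maps, or from an
emulated manual delineation that replays phantom ground truth with an
optional rater-error perturbation. Volumes are reported as infarct /
ipsilateral-hemisphere voxel ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .maps import QuantitativeMap, T2_UNITS
from .phantom import AtlasTemplate, LesionGroundTruth

__all__ = [
    "BinaryLesionMask",
    "VolumetryResult",
    "segment_infarct_t2",
    "remove_csf",
    "segment_manual_emulated",
    "volume_ratio",
]


@dataclass(frozen=True)
class BinaryLesionMask:
    mask: np.ndarray
    method: str  # "t2_threshold" | "manual_emulated"
    threshold_ms: Optional[float] = None
    timepoint: str = "24h"
    subject_id: str = "sub-00"

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class VolumetryResult:
    lesion_voxels: int
    hemisphere_voxels: int
    ratio: float
    voxel_volume_mm3: float

    @property
    def lesion_volume_mm3(self) -> float:
        return self.lesion_voxels * self.voxel_volume_mm3


def segment_infarct_t2(
    t2_map: QuantitativeMap,
    threshold_ms: float = 34.0,
    brain_mask: Optional[np.ndarray] = None,
    direction: str = "below",
    timepoint: str = "24h",
    subject_id: str = "sub-00",
    min_component_voxels: int = 0,
) -> BinaryLesionMask:
    """Threshold-based infarct segmentation of a quantitative T2 map.

    The mask is ``{x in brain & valid : T2(x) < threshold}`` (strict
    inequality; voxels exactly at the threshold are excluded, making the
    boundary deterministic). ``direction='above'`` selects the opposite
    comparison. Invalid voxels never enter the mask. Optional
    minimum-component filtering is off by default.
    """
    if t2_map.units != T2_UNITS:
        raise ValueError(f"T2 map units must be {T2_UNITS!r}, got {t2_map.units!r}")
    if brain_mask is None:
        brain_mask = np.ones(t2_map.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != t2_map.shape:
        raise ValueError("brain mask grid does not match the T2 map")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    if direction == "below":
        sel = t2_map.values < threshold_ms
    elif direction == "above":
        sel = t2_map.values > threshold_ms
    else:
        raise ValueError("direction must be 'below' or 'above'")
    mask = brain_mask & t2_map.validity_mask & sel
    if min_component_voxels > 0 and mask.any():
        labels, n = ndimage.label(mask)
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_component_voxels)
        keep = keep[keep > 0]
        mask = np.isin(labels, keep)
    return BinaryLesionMask(mask, "t2_threshold", float(threshold_ms), timepoint, subject_id)


def remove_csf(lesion: BinaryLesionMask, ventricle_mask: np.ndarray) -> BinaryLesionMask:
    """Remove intraventricular CSF voxels from a lesion mask (idempotent)."""
    vent = np.asarray(ventricle_mask, dtype=bool)
    if vent.shape != lesion.mask.shape:
        raise ValueError("ventricle mask grid does not match the lesion mask")
    return replace(lesion, mask=lesion.mask & ~vent)


def segment_manual_emulated(
    ground_truth: LesionGroundTruth,
    timepoint: str,
    rater_error_voxels: int = 0,
    boundary_jitter_prob: float = 0.0,
    seed: int = 0,
    subject_id: str = "sub-00",
) -> BinaryLesionMask:
    """Emulated manual delineation: phantom ground truth plus rater error.

    ``rater_error_voxels`` dilates (positive) or erodes (negative) the
    ground-truth mask by that many voxels; ``boundary_jitter_prob``
    additionally flips boundary voxels with the given probability using the
    seeded generator, so emulated raters are reproducible.
    """
    if ground_truth is None:
        raise ValueError("manual-emulated segmentation requires phantom ground truth")
    mask = ground_truth.mask(timepoint).copy()
    structure = ndimage.generate_binary_structure(3, 1)
    if rater_error_voxels > 0:
        mask = ndimage.binary_dilation(mask, structure, iterations=rater_error_voxels)
    elif rater_error_voxels < 0:
        mask = ndimage.binary_erosion(mask, structure, iterations=-rater_error_voxels)
    if boundary_jitter_prob > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        outer = ndimage.binary_dilation(mask, structure) & ~mask
        inner = mask & ~ndimage.binary_erosion(mask, structure)
        flips = rng.random(mask.shape) < boundary_jitter_prob
        mask = mask | (outer & flips)
        mask = mask & ~(inner & flips)
    return BinaryLesionMask(mask, "manual_emulated", None, timepoint, subject_id)


def volume_ratio(
    lesion: BinaryLesionMask,
    template: AtlasTemplate,
    side: str = "ipsilateral",
) -> VolumetryResult:
    """Infarct / hemisphere volume ratio in atlas space.

    The denominator is the ipsilateral (right) hemisphere; lesion voxels
    outside that hemisphere trigger a diagnostic warning and are excluded
    from the numerator, keeping the ratio in [0, 1].
    """
    if side != "ipsilateral":
        raise ValueError("only the ipsilateral hemisphere denominator is defined")
    if lesion.mask.shape != template.shape:
        raise ValueError("lesion mask is not in atlas space")
    hemi = template.right_hemisphere_mask
    n_hemi = int(hemi.sum())
    if n_hemi == 0:
        raise ValueError("empty hemisphere label")
    inside = int((lesion.mask & hemi).sum())
    outside = int(lesion.mask.sum()) - inside
    if outside > 0:
        warnings.warn(
            f"{outside} lesion voxels lie outside the ipsilateral hemisphere "
            "and are excluded from the volume ratio",
            stacklevel=2,
        )
    return VolumetryResult(
        lesion_voxels=inside,
        hemisphere_voxels=n_hemi,
        ratio=inside / n_hemi,
        voxel_volume_mm3=template.geometry.voxel_volume_mm3,
    )
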