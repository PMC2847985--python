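"""Rigid 6-DOF transforms and grid resampling.

A :class:`RigidTransform` maps moving-world coordinates (mm) to fixed-world
coordinates: ``w' = R (w - c) + c + t`` with ``R`` built from three Euler
angles applied about the fixed axes in x-y-z order, ``c`` the rotation
center (volume center by convention) and ``t`` a translation in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import AcquisitionGeometry

__all__ = ["RigidTransform", "resample", "resample_series", "resample_validity"]

_CONVENTION = "euler-xyz-deg/translation-mm/center-volume-mm/moving-to-fixed"


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body (3 rotations + 3 translations) world transform."""

    rotations_deg: Tuple[float, float, float]
    translations_mm: Tuple[float, float, float]
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0), tuple(float(c) for c in center_mm))

    @property
    def is_identity(self) -> bool:
        return (
            max(abs(a) for a in self.rotations_deg) < 1e-12
            and max(abs(t) for t in self.translations_mm) < 1e-12
        )

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotations_deg, degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world matrix."""
        rot = self.rotation_matrix()
        c = np.asarray(self.center_mm, dtype=float)
        t = np.asarray(self.translations_mm, dtype=float)
        mat = np.eye(4)
        mat[:3, :3] = rot
        mat[:3, 3] = c + t - rot @ c
        return mat

    @classmethod
    def from_matrix(cls, mat: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        rot = np.asarray(mat)[:3, :3]
        angles = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(mat)[:3, 3] - c + rot @ c
        return cls(tuple(float(a) for a in angles), tuple(float(v) for v in t), tuple(float(v) for v in c))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), self.center_mm)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), self.center_mm)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        mat = self.matrix()
        return pts @ mat[:3, :3].T + mat[:3, 3]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotations_deg": list(self.rotations_deg),
            "translations_mm": list(self.translations_mm),
            "center_mm": list(self.center_mm),
            "convention": _CONVENTION,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotations_deg"]), tuple(d["translations_mm"]), tuple(d["center_mm"]))

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


_ORDERS = {"trilinear": 1, "nearest": 0}


def _voxel_mapping(
    transform: RigidTransform,
    source_geometry: AcquisitionGeometry,
    target_geometry: AcquisitionGeometry,
) -> Tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping target voxel indices to source voxel indices.

    ``transform`` maps source(moving)-world to target(fixed)-world; sampling
    therefore pulls through its inverse.
    """
    d_src = np.diag(source_geometry.spacing_mm)
    d_tgt = np.diag(target_geometry.spacing_mm)
    mat = transform.matrix()
    rot, b = mat[:3, :3], mat[:3, 3]
    rot_inv = rot.T  # rotations are orthonormal
    a = np.linalg.solve(d_src, rot_inv @ d_tgt)
    offset = np.linalg.solve(d_src, rot_inv @ (-b))
    return a, offset


def resample(
    volume: np.ndarray,
    transform: RigidTransform,
    source_geometry: AcquisitionGeometry,
    target_geometry: Optional[AcquisitionGeometry] = None,
    interpolation: str = "trilinear",
    fill: float = 0.0,
    allow_label_trilinear: bool = False,
) -> np.ndarray:
    """Resample ``volume`` (on the source grid) onto the target grid.

    ``transform`` maps moving(source)-world to fixed(target)-world in mm.
    Out-of-field voxels receive ``fill`` and should be excluded downstream
    via :func:`resample_validity`.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation mode {interpolation!r}")
    if target_geometry is None:
        target_geometry = source_geometry
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("resample expects a 3-D volume; use resample_series for 4-D")
    is_label = vol.dtype == bool or np.issubdtype(vol.dtype, np.integer)
    if is_label and interpolation == "trilinear" and not allow_label_trilinear:
        raise ValueError(
            "trilinear interpolation on a label/mask volume mixes codes; "
            "use interpolation='nearest' (or allow_label_trilinear=True)"
        )
    if transform.is_identity and target_geometry.shape == source_geometry.shape:
        return vol.copy()
    a, offset = _voxel_mapping(transform, source_geometry, target_geometry)
    work = vol.astype(float) if is_label and interpolation == "trilinear" else vol
    out = ndimage.affine_transform(
        work,
        a,
        offset=offset,
        output_shape=target_geometry.shape,
        order=_ORDERS[interpolation],
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return out


def resample_series(volume4d: np.ndarray, transform: RigidTransform, source_geometry,
                    target_geometry=None, interpolation: str = "trilinear", fill: float = 0.0) -> np.ndarray:
    """Apply :func:`resample` frame-by-frame along the last axis of a 4-D series."""
    vol = np.asarray(volume4d)
    if vol.ndim != 4:
        raise ValueError("resample_series expects a 4-D volume")
    frames = [
        resample(vol[..., k], transform, source_geometry, target_geometry, interpolation, fill)
        for k in range(vol.shape[-1])
    ]
    return np.stack(frames, axis=-1)


def resample_validity(transform: RigidTransform, source_geometry,
                      target_geometry=None) -> np.ndarray:
    """Boolean mask of target voxels whose pull-back lies inside the source FOV."""
    ones = np.ones(source_geometry.shape, dtype=float)
    mapped = resample(ones, transform, source_geometry, target_geometry,
                      interpolation="trilinear", fill=0.0)
    return mapped >= 1.0 - 1e-6
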