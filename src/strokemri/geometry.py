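"""Acquisition geometry shared by the phantom generator and the analysis.

The default geometry reproduces a small-animal multimodal stroke protocol at
ultra-high field: a 64x64 in-plane matrix over a 2.5x2.5 cm field of view,
13 coronal slices of 0.5 mm thickness on a 1 mm slice-to-slice pitch, a
32-echo CPMG train with 4.2 ms echo spacing, diffusion weightings b = 0 and
800 s/mm^2, and a CASL control/label pair.

Conventions: arrays are indexed (x, y, z) with x the left-right axis
(larger x = right hemisphere), y the in-plane dorso-ventral axis and z the
slice (rostro-caudal) axis; world coordinates are millimetres, 0-based voxel
index times voxel spacing, RAS-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

import numpy as np

__all__ = ["AcquisitionGeometry", "DEFAULT_GEOMETRY"]


_DEFAULT_TR_MS: Mapping[str, float] = {
    "cpmg": 2000.0,
    "dwi": 2000.0,
    "casl": 1000.0,
    "ir": 10000.0,
}

# Signal averages per sequence: the CASL pair is averaged over 12
# repetitions and the b=800 DWI over 3, per the emulated protocol.
_DEFAULT_AVERAGES: Mapping[str, int] = {
    "cpmg": 1,
    "dwi_b0": 1,
    "dwi_b800": 3,
    "casl": 12,
    "ir": 1,
}

# Inversion times for the (synthetic) inversion-recovery T1 series, ms.
_DEFAULT_TI_MS: Tuple[float, ...] = (100.0, 300.0, 800.0, 1500.0, 3000.0, 6000.0)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Grid and sequence-timing description of one multimodal acquisition."""

    matrix_size: Tuple[int, int] = (64, 64)
    fov_mm: Tuple[float, float] = (25.0, 25.0)
    n_slices: int = 13
    slice_thickness_mm: float = 0.5
    interslice_distance_mm: float = 1.0
    echo_spacing_ms: float = 4.2
    n_echoes: int = 32
    b_values_s_per_mm2: Tuple[float, float] = (0.0, 800.0)
    tr_ms: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TR_MS))
    averages: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_AVERAGES))
    ir_inversion_times_ms: Tuple[float, ...] = _DEFAULT_TI_MS
    dwi_te_ms: float = 22.3
    casl_te_ms: float = 17.2

    def __post_init__(self) -> None:
        nx, ny = self.matrix_size
        if nx <= 0 or ny <= 0 or self.n_slices <= 0:
            raise ValueError("matrix_size and n_slices must be positive")
        if min(self.fov_mm) <= 0:
            raise ValueError("fov_mm must be positive")
        if self.slice_thickness_mm <= 0 or self.interslice_distance_mm <= 0:
            raise ValueError("slice geometry must be positive")
        # The T2 fit consumes the first 20 echoes of the CPMG train.
        if self.n_echoes < 20:
            raise ValueError("n_echoes must be >= 20")
        if self.echo_spacing_ms <= 0:
            raise ValueError("echo_spacing_ms must be positive")
        bvals = tuple(self.b_values_s_per_mm2)
        n_zero = sum(1 for b in bvals if b == 0)
        n_pos = sum(1 for b in bvals if b > 0)
        if len(bvals) != 2 or n_zero != 1 or n_pos != 1:
            raise ValueError("b_values must contain exactly one zero and one positive value")

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.matrix_size[0], self.matrix_size[1], self.n_slices)

    @property
    def spacing_mm(self) -> Tuple[float, float, float]:
        """Voxel spacing (sampling pitch) along x, y, z in mm."""
        return (
            self.fov_mm[0] / self.matrix_size[0],
            self.fov_mm[1] / self.matrix_size[1],
            self.interslice_distance_mm,
        )

    @property
    def voxel_volume_mm3(self) -> float:
        """Sampled volume per voxel (in-plane pixel area times slice pitch)."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def echo_times_ms(self) -> np.ndarray:
        """CPMG echo times TE_k = k * echo_spacing, k = 1..n_echoes."""
        return self.echo_spacing_ms * np.arange(1, self.n_echoes + 1, dtype=float)

    @property
    def b_value_s_per_mm2(self) -> float:
        """The single positive diffusion weighting."""
        return max(self.b_values_s_per_mm2)

    @property
    def center_mm(self) -> Tuple[float, float, float]:
        """Volume center in world mm (rotation-center convention)."""
        dx, dy, dz = self.spacing_mm
        nx, ny, nz = self.shape
        return ((nx - 1) / 2 * dx, (ny - 1) / 2 * dy, (nz - 1) / 2 * dz)

    def affine(self) -> np.ndarray:
        """NIfTI-style voxel-to-world affine (diagonal, origin at voxel 0)."""
        dx, dy, dz = self.spacing_mm
        return np.diag([dx, dy, dz, 1.0])

    def with_matrix(self, nx: int, ny: int, n_slices: int) -> "AcquisitionGeometry":
        """Same protocol on a different grid (FOV preserved)."""
        return replace(self, matrix_size=(nx, ny), n_slices=n_slices)


DEFAULT_GEOMETRY = AcquisitionGeometry()
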