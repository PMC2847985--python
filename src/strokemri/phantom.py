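"""Digital mouse-brain phantom: template, lesions, tissue fields, cohorts.

The generator stands in for the animal study it emulates: two inbred-strain
groups of 8 mice imaged 2 h and 24 h after transient middle-cerebral-artery
occlusion. A deterministic ellipsoidal brain template carries hemisphere,
cortical-MCA, subcortical and ventricle labels; lesions grow from the
subcortical territory into a connected fraction of the cortical MCA band,
nested over time; tissue parameter fields (T2, T1, ADC, CBF, proton-density
scale) are piecewise constant per compartment with ROI-level values drawn
from between-subject distributions; raw acquisitions are synthesized by the
forward signal models matching the analysis (CPMG decay, two-point
diffusion attenuation, the inverse of the single-compartment CASL formula,
magnitude inversion recovery), posed under a rigid misalignment, and
corrupted by Rician noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, DEFAULT_GEOMETRY
from .maps import CASLModelConstants
from .transforms import RigidTransform

__all__ = [
    "LABELS",
    "AtlasTemplate",
    "LesionGroundTruth",
    "TissueValues",
    "TissueParameterField",
    "SubjectRawData",
    "SyntheticSubject",
    "GroupSpec",
    "build_template",
    "make_lesion",
    "make_tissue_field",
    "synthesize_subject",
    "synthesize_cohort",
    "default_group_spec",
    "add_rician_noise",
    "derive_seed",
]

# Label codes of the atlas volume.
LABELS = {
    "background": 0,
    "left_hemisphere": 1,
    "right_hemisphere": 2,
    "cortex_mca": 3,
    "subcortex": 4,
    "ventricle": 5,
}

TIMEPOINTS = ("2h", "24h")

DEFAULT_SEGMENTATION_THRESHOLD_MS = 34.0
DEFAULT_T2_MARGIN_MS = 2.0


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtlasTemplate:
    """Integer label volume plus a reference intensity image in atlas space."""

    labels: np.ndarray
    geometry: AcquisitionGeometry
    reference_intensity: np.ndarray

    @property
    def shape(self):
        return self.labels.shape

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def right_hemisphere_mask(self) -> np.ndarray:
        """Ipsilateral (right) hemisphere: all brain voxels with x past midline."""
        nx = self.shape[0]
        x_right = np.arange(nx)[:, None, None] > (nx - 1) / 2
        return self.brain_mask & np.broadcast_to(x_right, self.shape)

    @property
    def left_hemisphere_mask(self) -> np.ndarray:
        return self.brain_mask & ~self.right_hemisphere_mask

    @property
    def cortex_mca_mask(self) -> np.ndarray:
        return self.label_mask("cortex_mca")

    @property
    def subcortex_mask(self) -> np.ndarray:
        return self.label_mask("subcortex")

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.label_mask("ventricle")

    def roi_mask(self, roi: str) -> np.ndarray:
        if roi in ("cortex", "cortex_mca"):
            return self.cortex_mca_mask
        if roi in ("subcortex", "subcortical"):
            return self.subcortex_mask
        raise KeyError(f"unknown ROI {roi!r}")


def _normalized_coords(geometry: AcquisitionGeometry):
    nx, ny, nz = geometry.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx, dtype=float), np.arange(ny, dtype=float), np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return ii, jj, kk, cx, cy, cz


def _s0_texture(geometry: AcquisitionGeometry, coords=None) -> np.ndarray:
    """Smooth deterministic proton-density modulation.

    Low-frequency sinusoidal texture plus a radial intensity profile tied to
    the brain ellipsoid; both give the otherwise piecewise-constant phantom
    the smooth internal structure that intensity-based registration locks
    onto in real anatomy. ``coords`` may supply fractional atlas voxel
    coordinates (3-tuple of arrays) for posed analytic evaluation.
    """
    nx, ny, nz = geometry.shape
    if coords is None:
        ii, jj, kk, cx, cy, cz = _normalized_coords(geometry)
    else:
        ii, jj, kk = coords
        cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    u, v, w = ii / nx, jj / ny, kk / max(nz, 1)
    mod = (
        1.0
        + 0.12 * np.sin(2 * np.pi * (1.7 * u + 0.13)) * np.cos(2 * np.pi * (1.3 * v + 0.41))
        + 0.08 * np.cos(2 * np.pi * (0.9 * w + 0.27))
        + 0.06 * np.sin(2 * np.pi * (0.8 * u + 1.1 * v))
    )
    ax, ay, az = 0.375 * nx, 0.28 * ny, 0.62 * nz
    r2 = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2
    mod *= 1.0 - 0.25 * np.clip(r2, 0.0, 1.3)
    return mod


def _evaluate_regions(geometry: AcquisitionGeometry, coords=None) -> Dict[str, np.ndarray]:
    """Evaluate the analytic anatomy at (possibly fractional) voxel coords.

    The phantom is defined by closed-form inequalities on atlas voxel
    coordinates, so it can be sampled at arbitrary continuous positions —
    this is how misaligned acquisitions are synthesized without
    interpolation blur. On the integer grid this reproduces the template
    labels exactly. Returns disjoint region masks with the precedence
    ventricle > subcortex > cortex already applied.
    """
    nx, ny, nz = geometry.shape
    if coords is None:
        ii, jj, kk, cx, cy, cz = _normalized_coords(geometry)
    else:
        ii, jj, kk = coords
        cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    ax, ay, az = 0.375 * nx, 0.28 * ny, 0.62 * nz
    r2 = ((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2
    brain = r2 <= 1.0
    right = ii > cx

    # in-plane radius normalized to the per-slice ellipse boundary
    z_scale2 = np.clip(1.0 - ((kk - cz) / az) ** 2, 1e-9, None)
    s = np.sqrt((((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2) / z_scale2)

    central = np.abs(kk - cz) <= 0.34 * nz

    # ventricles: small deep medial ellipsoids, one per hemisphere
    vent = np.zeros(np.shape(ii), dtype=bool)
    for sign in (-1.0, 1.0):
        vx, vy = cx + sign * 0.075 * nx, cy - 0.05 * ny
        vent |= (
            ((ii - vx) / (0.035 * nx)) ** 2
            + ((jj - vy) / (0.06 * ny)) ** 2
            + ((kk - cz) / (0.30 * nz)) ** 2
        ) <= 1.0
    vent &= brain

    # subcortical ROI: deep ellipsoid in the right hemisphere
    sx, sy = cx + 0.16 * nx, cy + 0.02 * ny
    subcortex = (
        ((ii - sx) / (0.115 * nx)) ** 2
        + ((jj - sy) / (0.13 * ny)) ** 2
        + ((kk - cz) / (0.34 * nz)) ** 2
    ) <= 1.0
    subcortex &= brain & right & ~vent

    # cortical MCA ROI: lateral superficial band of the right hemisphere
    lateral = (ii - cx) / ax >= 0.28 * np.sqrt(z_scale2)
    cortex = brain & right & central & lateral & (s >= 0.70) & ~vent & ~subcortex

    return {"brain": brain, "right": right, "ventricle": vent,
            "subcortex": subcortex, "cortex": cortex}


def build_template(geometry: AcquisitionGeometry = DEFAULT_GEOMETRY) -> AtlasTemplate:
    """Construct the deterministic digital mouse-brain label template.

    The brain is an ellipsoid; the cortical-MCA ROI is a lateral superficial
    band of the right hemisphere, the subcortical ROI (caudoputamen +
    pyramidal tract analogue) a deep right-hemisphere ellipsoid, and a small
    medial ventricle sits in each hemisphere. Together the two ROIs span
    roughly the MCA territory (~45 % of the hemisphere). Construction is
    pure arithmetic on voxel indices, hence bit-reproducible.
    """
    nx, ny, nz = geometry.shape
    if min(nx, ny) < 16:
        raise ValueError("in-plane matrix too small to host all template labels (>= 16 required)")

    regions = _evaluate_regions(geometry)
    brain, right = regions["brain"], regions["right"]
    vent, subcortex, cortex = regions["ventricle"], regions["subcortex"], regions["cortex"]

    labels = np.zeros(geometry.shape, dtype=np.int16)
    labels[brain & ~right] = LABELS["left_hemisphere"]
    labels[brain & right] = LABELS["right_hemisphere"]
    labels[cortex] = LABELS["cortex_mca"]
    labels[subcortex] = LABELS["subcortex"]
    labels[vent] = LABELS["ventricle"]

    present = set(np.unique(labels).tolist())
    if present != set(LABELS.values()):
        raise ValueError(f"template geometry too coarse: labels {sorted(present)} present")

    reference = _reference_intensity(labels, geometry)
    return AtlasTemplate(labels=labels, geometry=geometry, reference_intensity=reference)


def _reference_intensity(labels: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """T2-weighted-like template image of the healthy brain (echo-1 contrast)."""
    values = TissueValues()
    te1 = geometry.echo_spacing_ms
    img = np.zeros(labels.shape, dtype=float)
    tissue = (labels > 0) & (labels != LABELS["ventricle"])
    img[tissue] = values.s0_tissue * math.exp(-te1 / values.t2_healthy_ms)
    csf = labels == LABELS["ventricle"]
    img[csf] = values.s0_csf * math.exp(-te1 / values.t2_csf_ms)
    img *= _s0_texture(geometry)
    img[labels == 0] = 0.0
    return img


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionGroundTruth:
    """Nested 2 h / 24 h infarct masks in atlas space."""

    lesion_mask_2h: np.ndarray
    lesion_mask_24h: np.ndarray
    strain_label: str
    cortical_fraction_2h: float
    cortical_fraction_24h: float
    subcortical_fraction_2h: float = 1.0
    subcortical_fraction_24h: float = 1.0

    def mask(self, timepoint: str) -> np.ndarray:
        if timepoint == "2h":
            return self.lesion_mask_2h
        if timepoint == "24h":
            return self.lesion_mask_24h
        raise KeyError(f"unknown timepoint {timepoint!r}")


def _growth_order(roi_mask: np.ndarray, seed_point: Tuple[int, int, int],
                  rng: np.random.Generator) -> np.ndarray:
    """Deterministic growth ordering of ROI voxels: BFS depth from the seed
    (6-connectivity), random jitter breaking ties inside each BFS layer.
    Unreachable ROI voxels (if any) are appended last in index order, so a
    fraction of 1 always covers the full ROI. Prefixes of the ordering are
    connected and nested by construction."""
    roi_idx = np.argwhere(roi_mask)
    n = len(roi_idx)
    depth = np.full(roi_mask.shape, -1, dtype=int)
    structure = ndimage.generate_binary_structure(3, 1)
    frontier = np.zeros(roi_mask.shape, dtype=bool)
    frontier[tuple(seed_point)] = True
    d = 0
    depth[frontier] = 0
    while frontier.any():
        grown = ndimage.binary_dilation(frontier, structure=structure) & roi_mask & (depth < 0)
        d += 1
        depth[grown] = d
        frontier = grown
    depths = depth[tuple(roi_idx.T)]
    unreached = depths < 0
    depths = np.where(unreached, depths.max() + 2 if n else 0, depths)
    jitter = rng.random(n)
    # lexsort: primary key depth, secondary jitter, final tie-break voxel index
    order = np.lexsort((np.arange(n), jitter, depths))
    return roi_idx[order]


def make_lesion(
    template: AtlasTemplate,
    cortical_fraction_2h: float = 0.57,
    cortical_fraction_24h: float = 0.94,
    subcortical_fraction_2h: float = 1.0,
    subcortical_fraction_24h: float = 1.0,
    rng_seed: int = 0,
    strain_label: str = "C57Bl/6",
) -> LesionGroundTruth:
    """Grow nested 2 h / 24 h lesions over the subcortical and cortical ROIs.

    Each timepoint's lesion is the union of a connected ``subcortical_fraction``
    of the subcortical ROI (grown from its centroid) and a connected
    ``cortical_fraction`` of the cortical-MCA ROI (grown from the cortical
    voxel nearest the subcortex, emulating the spread of infarction from the
    basal ganglia into the cortex). One shared growth ordering per ROI makes
    the 2 h lesion a subset of the 24 h lesion whenever the 24 h fractions
    are at least the 2 h fractions (enforced).
    """
    for f in (cortical_fraction_2h, cortical_fraction_24h,
              subcortical_fraction_2h, subcortical_fraction_24h):
        if not (0.0 <= f <= 1.0):
            raise ValueError("lesion fractions must lie in [0, 1]")
    cortical_fraction_24h = max(cortical_fraction_24h, cortical_fraction_2h)
    subcortical_fraction_24h = max(subcortical_fraction_24h, subcortical_fraction_2h)

    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
    cortex = template.cortex_mca_mask
    subcortex = template.subcortex_mask

    sub_idx = np.argwhere(subcortex)
    sub_centroid = sub_idx.mean(axis=0)
    sub_seed = sub_idx[np.argmin(((sub_idx - sub_centroid) ** 2).sum(axis=1))]

    cor_idx = np.argwhere(cortex)
    cor_seed = cor_idx[np.argmin(((cor_idx - sub_centroid) ** 2).sum(axis=1))]

    # one ordering per ROI, shared across timepoints (nestedness)
    sub_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    cor_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
    sub_order = _growth_order(subcortex, tuple(sub_seed), sub_rng)
    cor_order = _growth_order(cortex, tuple(cor_seed), cor_rng)

    def assemble(f_sub, f_cor):
        out = np.zeros(template.shape, dtype=bool)
        k_sub = int(round(f_sub * len(sub_order)))
        k_cor = int(round(f_cor * len(cor_order)))
        if k_sub:
            out[tuple(sub_order[:k_sub].T)] = True
        if k_cor:
            out[tuple(cor_order[:k_cor].T)] = True
        return out

    mask_2h = assemble(subcortical_fraction_2h, cortical_fraction_2h)
    mask_24h = assemble(subcortical_fraction_24h, cortical_fraction_24h)
    _ = rng  # reserved: rng_seed spawns the per-ROI tie-break streams above
    return LesionGroundTruth(
        lesion_mask_2h=mask_2h,
        lesion_mask_24h=mask_24h,
        strain_label=strain_label,
        cortical_fraction_2h=float(cortical_fraction_2h),
        cortical_fraction_24h=float(cortical_fraction_24h),
        subcortical_fraction_2h=float(subcortical_fraction_2h),
        subcortical_fraction_24h=float(subcortical_fraction_24h),
    )


# ---------------------------------------------------------------------------
# tissue parameter fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueValues:
    """Per-compartment ground-truth tissue parameter levels.

    T2/T1 distinguish healthy tissue, infarct and CSF; ADC and CBF are set
    per ROI (cortical-MCA, subcortical) because the study reports them as
    ROI means, with a healthy level elsewhere. Units: ms, mm^2/s,
    mL/100 g/min; s0 is an arbitrary proton-density scale.
    """

    t2_healthy_ms: float = 45.0
    t2_infarct_ms: float = 30.0
    t2_csf_ms: float = 80.0
    t1_healthy_ms: float = 2200.0
    t1_infarct_ms: float = 2400.0
    t1_csf_ms: float = 4500.0
    adc_healthy_mm2_per_s: float = 8.0e-4
    adc_cortex_roi_mm2_per_s: float = 7.8e-4
    adc_subcortex_roi_mm2_per_s: float = 7.3e-4
    adc_csf_mm2_per_s: float = 2.8e-3
    cbf_healthy: float = 110.0
    cbf_cortex_roi: float = 34.1
    cbf_subcortex_roi: float = 30.4
    cbf_csf: float = 10.0
    s0_tissue: float = 1000.0
    s0_csf: float = 1400.0

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class TissueParameterField:
    """Voxel-wise ground-truth parameter volumes on the atlas grid."""

    t2_ms: np.ndarray
    t1_ms: np.ndarray
    adc_mm2_per_s: np.ndarray
    cbf_ml_per_100g_min: np.ndarray
    s0: np.ndarray
    values: TissueValues
    lesion_mask: np.ndarray

    def field(self, name: str) -> np.ndarray:
        return getattr(self, name)


def make_tissue_field(
    template: AtlasTemplate,
    lesion_mask: np.ndarray,
    values: TissueValues = TissueValues(),
    texture: bool = True,
    segmentation_threshold_ms: float = DEFAULT_SEGMENTATION_THRESHOLD_MS,
    t2_margin_ms: float = DEFAULT_T2_MARGIN_MS,
) -> TissueParameterField:
    """Assemble voxel-wise parameter volumes from compartment levels.

    Enforces the separability contract of the phantom: infarct T2 stays below
    the segmentation threshold minus a margin, healthy tissue above threshold
    plus margin, so noise-free threshold segmentation is exact by design.
    """
    if values.t2_infarct_ms >= segmentation_threshold_ms - t2_margin_ms:
        raise ValueError("infarct T2 must sit below the segmentation threshold minus the margin")
    if values.t2_healthy_ms <= segmentation_threshold_ms + t2_margin_ms:
        raise ValueError("healthy T2 must sit above the segmentation threshold plus the margin")
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != template.shape:
        raise ValueError("lesion mask grid does not match the template")

    regions = {
        "brain": template.brain_mask,
        "ventricle": template.ventricle_mask,
        "cortex": template.cortex_mca_mask,
        "subcortex": template.subcortex_mask,
    }
    texture_arr = _s0_texture(template.geometry) if texture else None
    fields, lesion = _assemble_fields(regions, lesion_mask, values, texture_arr)
    return TissueParameterField(t2_ms=fields["t2"], t1_ms=fields["t1"],
                                adc_mm2_per_s=fields["adc"],
                                cbf_ml_per_100g_min=fields["cbf"], s0=fields["s0"],
                                values=values, lesion_mask=lesion)


def _assemble_fields(regions: Dict[str, np.ndarray], lesion_mask: np.ndarray,
                     values: TissueValues, texture_arr: Optional[np.ndarray]):
    """Compartment levels -> voxel-wise parameter volumes.

    T2/T1 follow the healthy/infarct/CSF compartments; ADC/CBF carry ROI-level
    values on the cortical and subcortical territories (the phantom's
    ground-truth analogue of the ROI means the study reports); s0 carries the
    texture modulation. Works on any region masks (integer grid or posed
    analytic evaluation).
    """
    brain, vent = regions["brain"], regions["ventricle"]
    cortex, subcortex = regions["cortex"], regions["subcortex"]
    tissue_m = brain & ~vent
    lesion = np.asarray(lesion_mask, dtype=bool) & tissue_m
    shape = brain.shape

    def compartment(healthy, infarct, csf):
        out = np.zeros(shape, dtype=float)
        out[tissue_m] = healthy
        out[lesion] = infarct
        out[vent] = csf
        return out

    def roiwise(healthy, cortex_val, subcortex_val, csf):
        out = np.zeros(shape, dtype=float)
        out[tissue_m] = healthy
        out[cortex] = cortex_val
        out[subcortex] = subcortex_val
        out[vent] = csf
        return out

    s0 = np.zeros(shape, dtype=float)
    s0[tissue_m] = values.s0_tissue
    s0[vent] = values.s0_csf
    if texture_arr is not None:
        s0 *= texture_arr
    fields = {
        "t2": compartment(values.t2_healthy_ms, values.t2_infarct_ms, values.t2_csf_ms),
        "t1": compartment(values.t1_healthy_ms, values.t1_infarct_ms, values.t1_csf_ms),
        "adc": roiwise(values.adc_healthy_mm2_per_s, values.adc_cortex_roi_mm2_per_s,
                       values.adc_subcortex_roi_mm2_per_s, values.adc_csf_mm2_per_s),
        "cbf": roiwise(values.cbf_healthy, values.cbf_cortex_roi,
                       values.cbf_subcortex_roi, values.cbf_csf),
        "s0": s0,
    }
    return fields, lesion


def _sample_mask_nearest(mask: np.ndarray, coords) -> np.ndarray:
    """Nearest-voxel lookup of a boolean atlas mask at fractional coords."""
    ii, jj, kk = (np.rint(c).astype(int) for c in coords)
    inb = ((ii >= 0) & (ii < mask.shape[0])
           & (jj >= 0) & (jj < mask.shape[1])
           & (kk >= 0) & (kk < mask.shape[2]))
    out = np.zeros(np.shape(coords[0]), dtype=bool)
    out[inb] = mask[ii[inb], jj[inb], kk[inb]]
    return out


# ---------------------------------------------------------------------------
# raw data synthesis
# ---------------------------------------------------------------------------


@dataclass
class SubjectRawData:
    """One subject's simulated acquisitions on the subject grid."""

    echo_train: np.ndarray
    dwi_b0: np.ndarray
    dwi_b800: np.ndarray
    casl_control: np.ndarray
    casl_label: np.ndarray
    ir_series: np.ndarray
    brain_mask: np.ndarray
    geometry: AcquisitionGeometry
    misalignment: RigidTransform
    noise_sigma: float
    seed: int
    timepoint: str = "24h"
    subject_id: str = "sub-00"
    strain: str = "C57Bl/6"


def add_rician_noise(volume: np.ndarray, sigma: float, rng: np.random.Generator,
                     model: str = "rician") -> np.ndarray:
    """Magnitude (Rician) noise: modulus of the complex Gaussian-corrupted
    signal. With zero signal this reduces to Rayleigh noise of mean
    sigma * sqrt(pi/2). A plain additive Gaussian model is selectable."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    v = np.asarray(volume, dtype=float)
    if sigma == 0:
        return v.copy()
    if model == "rician":
        re = v + sigma * rng.standard_normal(v.shape)
        im = sigma * rng.standard_normal(v.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return v + sigma * rng.standard_normal(v.shape)
    raise ValueError(f"unknown noise model {model!r}")


def derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2**31) from a tuple of integer keys."""
    state = np.random.SeedSequence(list(keys)).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def synthesize_subject(
    template: AtlasTemplate,
    lesion: Optional[LesionGroundTruth],
    tissue: TissueParameterField,
    geometry: Optional[AcquisitionGeometry] = None,
    noise_sigma: float = 0.0,
    misalignment: Optional[RigidTransform] = None,
    seed: int = 0,
    timepoint: str = "24h",
    subject_id: str = "sub-00",
    strain: str = "C57Bl/6",
    noise_model: str = "rician",
    casl_constants: CASLModelConstants = CASLModelConstants(),
) -> SubjectRawData:
    """Forward-simulate one subject's multimodal acquisition.

    Signal models (noise-free): CPMG echoes ``s0 exp(-TE_k/T2)``; DWI
    ``s0' exp(-b ADC)``; the CASL pair is built by inverting the
    analysis-side quantification, so applying the CASL formula with the true
    T1 returns the ground-truth CBF exactly; IR series
    ``|s0 (1 - 2 exp(-TI/T1))|``. The subject's pose is realized by
    evaluating the analytic phantom at the rigidly transformed voxel
    positions (``misalignment`` maps subject world to atlas world), i.e.
    each subject voxel samples the phantom at its true location, exactly as
    a scanner would — no interpolation of voxel data is involved. Magnitude
    (Rician) noise is added last; the seed fully determines all draws.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if geometry is None:
        geometry = template.geometry
    if misalignment is None:
        misalignment = RigidTransform.identity(geometry.center_mm)

    src = template.geometry
    if misalignment.is_identity and src.shape == geometry.shape:
        f = {"t2": tissue.t2_ms, "t1": tissue.t1_ms, "adc": tissue.adc_mm2_per_s,
             "cbf": tissue.cbf_ml_per_100g_min, "s0": tissue.s0}
        brain = template.brain_mask.copy()
    else:
        nx, ny, nz = geometry.shape
        vi, vj, vk = np.meshgrid(np.arange(nx, dtype=float),
                                 np.arange(ny, dtype=float),
                                 np.arange(nz, dtype=float), indexing="ij")
        pts = np.stack([vi, vj, vk], axis=-1).reshape(-1, 3) * np.array(geometry.spacing_mm)
        atlas_pts = misalignment.apply(pts)
        coords = tuple(
            (atlas_pts[:, a] / src.spacing_mm[a]).reshape(geometry.shape) for a in range(3)
        )
        regions = _evaluate_regions(src, coords)
        lesion_posed = _sample_mask_nearest(tissue.lesion_mask, coords)
        texture_arr = _s0_texture(src, coords)
        f, _ = _assemble_fields(regions, lesion_posed, tissue.values, texture_arr)
        brain = regions["brain"]

    t2 = np.where(f["t2"] > 0, f["t2"], 1.0)
    t1 = np.where(f["t1"] > 0, f["t1"], 1.0)
    s0 = f["s0"]
    on = s0 > 0

    te = geometry.echo_times_ms
    echo = s0[..., None] * np.exp(-te[None, None, None, :] / t2[..., None])
    echo[~on] = 0.0

    b = geometry.b_value_s_per_mm2
    dwi0 = s0 * np.exp(-geometry.dwi_te_ms / t2)
    dwi0[~on] = 0.0
    dwib = dwi0 * np.exp(-b * f["adc"])

    ctrl = s0 * np.exp(-geometry.casl_te_ms / t2)
    ctrl[~on] = 0.0
    # inverse of the single-compartment CASL quantification
    frac = (
        f["cbf"]
        * 2.0
        * casl_constants.alpha
        * (t1 / 1000.0)
        / (6000.0 * casl_constants.lambda_ml_per_g)
    )
    lbl = ctrl * (1.0 - frac)

    ti = np.asarray(geometry.ir_inversion_times_ms, dtype=float)
    ir = np.abs(s0[..., None] * (1.0 - 2.0 * np.exp(-ti[None, None, None, :] / t1[..., None])))
    ir[~on] = 0.0

    # one independent, seed-derived noise stream per sequence; sequences with
    # multiple signal averages are simulated as the mean of that many
    # independently noisy repetitions (CASL x12, b=800 DWI x3 by default)
    streams = np.random.SeedSequence(seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]
    avg = geometry.averages

    def acquire(vol, rng, n_avg):
        reps = [add_rician_noise(vol, noise_sigma, rng, noise_model)
                for _ in range(max(1, int(n_avg)))]
        return reps[0] if len(reps) == 1 else np.mean(reps, axis=0)

    echo = acquire(echo, rngs[0], avg.get("cpmg", 1))
    dwi0 = acquire(dwi0, rngs[1], avg.get("dwi_b0", 1))
    dwib = acquire(dwib, rngs[2], avg.get("dwi_b800", 1))
    ctrl = acquire(ctrl, rngs[3], avg.get("casl", 1))
    lbl = acquire(lbl, rngs[4], avg.get("casl", 1))
    ir = acquire(ir, rngs[5], avg.get("ir", 1))

    return SubjectRawData(
        echo_train=echo, dwi_b0=dwi0, dwi_b800=dwib,
        casl_control=ctrl, casl_label=lbl, ir_series=ir,
        brain_mask=brain, geometry=geometry, misalignment=misalignment,
        noise_sigma=float(noise_sigma), seed=int(seed),
        timepoint=timepoint, subject_id=subject_id, strain=strain,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Between-subject distributions defining one strain group.

    ``tissue_means`` holds the per-timepoint compartment levels;
    ``lesion_fractions`` the (mean, SD) of the per-subject ROI infarct
    fractions; scalar tissue parameters are drawn as truncated normals with
    coefficient of variation ``between_subject_cv`` (T2 uses a tighter CV
    and is additionally truncated to respect the segmentation margins).
    """

    strain: str = "C57Bl/6"
    n_subjects: int = 8
    tissue_means: Mapping[str, TissueValues] = field(default_factory=dict)
    lesion_fractions: Mapping[str, Mapping[str, Tuple[float, float]]] = field(default_factory=dict)
    between_subject_cv: float = 0.15
    t2_cv: float = 0.05
    t1_cv: float = 0.10
    snr: Optional[float] = 40.0
    noise_sigma: Optional[float] = None
    misalignment_max_deg: float = 5.0
    misalignment_max_vox: float = 2.0
    misaligned: bool = True
    segmentation_threshold_ms: float = DEFAULT_SEGMENTATION_THRESHOLD_MS
    t2_margin_ms: float = DEFAULT_T2_MARGIN_MS

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


# Group-level tissue and lesion levels per strain and timepoint, taken from
# the study conditions this generator emulates (ROI CBF in mL/100 g/min, ADC
# in mm^2/s; lesion-fraction means chosen so that ROI infarct-probability
# summaries land at the reported 2 h / 24 h levels).
_STRAIN_TABLE = {
    "C57Bl/6": {
        "cbf": {"2h": (38.7, 32.8), "24h": (25.2, 23.4)},   # (cortex, subcortex)
        "adc": {"2h": (7.8e-4, 7.2e-4), "24h": (5.7e-4, 5.3e-4)},
        "cortical_fraction": {"2h": (0.607, 0.28), "24h": (0.951, 0.08)},
        "subcortical_fraction": {"2h": (0.791, 0.30), "24h": (1.0, 0.0)},
    },
    "Sv/129": {
        "cbf": {"2h": (34.1, 30.4), "24h": (22.3, 20.8)},
        "adc": {"2h": (7.8e-4, 7.3e-4), "24h": (5.8e-4, 5.4e-4)},
        "cortical_fraction": {"2h": (0.533, 0.28), "24h": (0.921, 0.08)},
        "subcortical_fraction": {"2h": (0.678, 0.30), "24h": (1.0, 0.0)},
    },
}


def default_group_spec(strain: str = "C57Bl/6", **overrides) -> GroupSpec:
    """Default study conditions for one strain (n = 8, SNR 40, +/-5 deg /
    +/-2 voxel misalignment, between-subject CV 15 %)."""
    if strain not in _STRAIN_TABLE:
        raise KeyError(f"unknown strain {strain!r}; expected one of {sorted(_STRAIN_TABLE)}")
    tab = _STRAIN_TABLE[strain]
    tissue_means = {
        tp: TissueValues(
            cbf_cortex_roi=tab["cbf"][tp][0],
            cbf_subcortex_roi=tab["cbf"][tp][1],
            adc_cortex_roi_mm2_per_s=tab["adc"][tp][0],
            adc_subcortex_roi_mm2_per_s=tab["adc"][tp][1],
        )
        for tp in TIMEPOINTS
    }
    lesion_fractions = {
        tp: {
            "cortical": tab["cortical_fraction"][tp],
            "subcortical": tab["subcortical_fraction"][tp],
        }
        for tp in TIMEPOINTS
    }
    kwargs = dict(strain=strain, tissue_means=tissue_means, lesion_fractions=lesion_fractions)
    kwargs.update(overrides)
    return GroupSpec(**kwargs)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float = 0.0, high: float = np.inf, max_tries: int = 1000) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if low < v < high or (v == low == 0.0):
            return float(v)
    return float(np.clip(mean, low, high))


_FIELD_CV_CLASS = {
    "t2_healthy_ms": "t2", "t2_infarct_ms": "t2", "t2_csf_ms": "t2",
    "t1_healthy_ms": "t1", "t1_infarct_ms": "t1", "t1_csf_ms": "t1",
    "adc_healthy_mm2_per_s": "cv", "adc_cortex_roi_mm2_per_s": "cv",
    "adc_subcortex_roi_mm2_per_s": "cv", "adc_csf_mm2_per_s": "cv",
    "cbf_healthy": "cv", "cbf_cortex_roi": "cv", "cbf_subcortex_roi": "cv",
    "cbf_csf": "cv", "s0_tissue": "cv", "s0_csf": "cv",
}


def _draw_subject_factors(rng: np.random.Generator, spec: GroupSpec) -> Dict[str, float]:
    """One multiplicative truncated-normal factor per tissue parameter.

    Drawn once per subject and shared across timepoints: between-subject
    variability is a property of the animal, so a subject's healthy-tissue
    parameters stay longitudinally consistent while the group-mean levels
    evolve with the infarct."""
    cvs = {"cv": spec.between_subject_cv, "t2": spec.t2_cv, "t1": spec.t1_cv}
    return {name: _trunc_normal(rng, 1.0, cvs[cls], low=0.0)
            for name, cls in _FIELD_CV_CLASS.items()}


def _apply_factors(means: TissueValues, factors: Mapping[str, float],
                   spec: GroupSpec) -> TissueValues:
    """Scale the group-mean compartment levels by the subject's factors,
    clipping T2 draws to the segmentation-margin bands the phantom
    guarantees (infarct strictly below threshold - margin, healthy and CSF
    strictly above threshold + margin)."""
    thr, margin = spec.segmentation_threshold_ms, spec.t2_margin_ms
    eps = 1e-6
    vals = {name: getattr(means, name) * factors[name] for name in _FIELD_CV_CLASS}
    vals["t2_healthy_ms"] = max(vals["t2_healthy_ms"], thr + margin + eps)
    vals["t2_csf_ms"] = max(vals["t2_csf_ms"], thr + margin + eps)
    vals["t2_infarct_ms"] = float(np.clip(vals["t2_infarct_ms"], 1.0, thr - margin - eps))
    return TissueValues(**vals)


@dataclass
class SyntheticSubject:
    """Paired 2 h / 24 h raw data plus full ground truth for one subject."""

    subject_id: str
    strain: str
    raw: Dict[str, SubjectRawData]
    lesion: LesionGroundTruth
    tissue: Dict[str, TissueParameterField]
    tissue_values: Dict[str, TissueValues]
    misalignment: Dict[str, RigidTransform]
    noise_sigma: float
    seed: int


def synthesize_cohort(
    spec: GroupSpec,
    template: Optional[AtlasTemplate] = None,
    master_seed: int = 0,
    group_index: int = 0,
    geometry: Optional[AcquisitionGeometry] = None,
    casl_constants: CASLModelConstants = CASLModelConstants(),
    timepoints: Sequence[str] = TIMEPOINTS,
) -> List[SyntheticSubject]:
    """Generate one strain group of paired 2 h / 24 h subjects.

    Seed scheme (documented counter convention): every random draw derives
    from ``SeedSequence([master_seed, group_index, subject_index, slot])``
    where slot 0 covers the subject's parameter/pose draws, slot 1 the
    lesion tie-breaks, and slots 10+tp the per-timepoint acquisition noise.
    Identical (spec, master_seed) therefore reproduces the cohort
    bit-identically.
    """
    if template is None:
        template = build_template(geometry or DEFAULT_GEOMETRY)
    geometry = geometry or template.geometry
    subjects: List[SyntheticSubject] = []
    for i in range(spec.n_subjects):
        par_rng = np.random.default_rng(np.random.SeedSequence([master_seed, group_index, i, 0]))

        fr = spec.lesion_fractions
        # the lesion tie-break seed is part of the between-subject
        # variability model: a fully degenerate fraction distribution must
        # produce identical subjects, so it collapses to a group-level seed
        degenerate = all(sd == 0 for rois in fr.values() for (_, sd) in rois.values())
        lesion_seed = (derive_seed(master_seed, group_index, 1) if degenerate
                       else derive_seed(master_seed, group_index, i, 1))
        f_cor_2h = _trunc_normal(par_rng, *fr["2h"]["cortical"], low=0.0, high=1.0)
        f_sub_2h = _trunc_normal(par_rng, *fr["2h"]["subcortical"], low=0.0, high=1.0)
        f_cor_24h = _trunc_normal(par_rng, *fr["24h"]["cortical"], low=0.0, high=1.0)
        f_sub_24h = _trunc_normal(par_rng, *fr["24h"]["subcortical"], low=0.0, high=1.0)
        lesion = make_lesion(
            template,
            cortical_fraction_2h=f_cor_2h,
            cortical_fraction_24h=max(f_cor_24h, f_cor_2h),
            subcortical_fraction_2h=f_sub_2h,
            subcortical_fraction_24h=max(f_sub_24h, f_sub_2h),
            rng_seed=lesion_seed,
            strain_label=spec.strain,
        )

        if spec.misaligned and (spec.misalignment_max_deg > 0 or spec.misalignment_max_vox > 0):
            dx, dy, dz = geometry.spacing_mm
            rot = par_rng.uniform(-spec.misalignment_max_deg, spec.misalignment_max_deg, 3)
            tvox = par_rng.uniform(-spec.misalignment_max_vox, spec.misalignment_max_vox, 3)
            trans = tvox * np.array([dx, dy, dz])
            pose = {
                tp: RigidTransform(tuple(rot + par_rng.uniform(-0.5, 0.5, 3)),
                                   tuple(trans + par_rng.uniform(-0.2, 0.2, 3)),
                                   geometry.center_mm)
                for tp in TIMEPOINTS
            }
        else:
            pose = {tp: RigidTransform.identity(geometry.center_mm) for tp in TIMEPOINTS}
        pose = {tp: pose[tp] for tp in timepoints}

        factors = _draw_subject_factors(par_rng, spec)

        raw: Dict[str, SubjectRawData] = {}
        tissue_fields: Dict[str, TissueParameterField] = {}
        tissue_vals: Dict[str, TissueValues] = {}
        sigma = 0.0
        for tp in timepoints:
            tp_index = TIMEPOINTS.index(tp)
            means = spec.tissue_means.get(tp, TissueValues())
            vals = _apply_factors(means, factors, spec)
            field_tp = make_tissue_field(
                template, lesion.mask(tp), vals,
                segmentation_threshold_ms=spec.segmentation_threshold_ms,
                t2_margin_ms=spec.t2_margin_ms,
            )
            if spec.noise_sigma is not None:
                sigma = spec.noise_sigma
            elif spec.snr:
                sigma = vals.s0_tissue / spec.snr
            else:
                sigma = 0.0
            raw[tp] = synthesize_subject(
                template, lesion, field_tp, geometry,
                noise_sigma=sigma,
                misalignment=pose[tp],
                seed=derive_seed(master_seed, group_index, i, 10 + tp_index),
                timepoint=tp,
                subject_id=f"{spec.strain}-{i:02d}",
                strain=spec.strain,
                casl_constants=casl_constants,
            )
            tissue_fields[tp] = field_tp
            tissue_vals[tp] = vals

        subjects.append(SyntheticSubject(
            subject_id=f"{spec.strain}-{i:02d}",
            strain=spec.strain,
            raw=raw,
            lesion=lesion,
            tissue=tissue_fields,
            tissue_values=tissue_vals,
            misalignment=pose,
            noise_sigma=sigma,
            seed=derive_seed(master_seed, group_index, i),
        ))
    return subjects
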