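"""End-to-end orchestration: simulate -> map -> register -> segment -> stats.

A single :class:`PipelineConfig` drives the whole run; identical config and
master seed reproduce the results JSON byte for byte (timestamps live only
in the log). Stage failures abort with a stage-labeled error; artifacts
written before the failure are retained for debugging.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from . import __version__
from .geometry import AcquisitionGeometry, DEFAULT_GEOMETRY
from .io import save_json, save_nifti
from .lesion import (BinaryLesionMask, remove_csf, segment_infarct_t2,
                     segment_manual_emulated, volume_ratio)
from .maps import (CASLModelConstants, QuantitativeMap, compute_adc_map,
                   compute_cbf_map, fit_t1_map, fit_t2_map)
from .phantom import (TIMEPOINTS, AtlasTemplate, GroupSpec, SyntheticSubject,
                      build_template, default_group_spec, synthesize_cohort)
from .register import extract_brain, register_rigid, to_atlas
from .stats import (ProbabilityMap, ROISummary, probability_map,
                    roi_mean_summary, roi_probability, wilcoxon_signed_rank_exact)
from .transforms import RigidTransform

__all__ = ["PipelineConfig", "CohortResult", "StageError", "run_pipeline",
           "render_reports", "default_config"]

logger = logging.getLogger("strokemri.pipeline")

ROIS = ("cortex", "subcortex")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    geometry: AcquisitionGeometry = DEFAULT_GEOMETRY
    groups: Tuple[GroupSpec, ...] = ()
    master_seed: int = 1234
    timepoints: Tuple[str, ...] = TIMEPOINTS
    n_echoes_used: int = 20
    alpha: float = 0.7
    lambda_ml_per_g: float = 0.95
    threshold_ms: float = 34.0
    threshold_direction: str = "below"
    registration: str = "stepwise"  # "stepwise" | "direct" | "identity"
    t1_source: str = "fit"  # "fit" | "fixed"
    fixed_t1_ms: float = 2200.0
    brain_extraction: str = "ground_truth"  # "ground_truth" | "automatic"
    rater_error_voxels: int = 0
    output_dir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("n_echoes_used", "alpha", "lambda_ml_per_g", "threshold_ms", "fixed_t1_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.registration not in ("stepwise", "direct", "identity"):
            raise ValueError("registration must be stepwise, direct or identity")

    @property
    def casl_constants(self) -> CASLModelConstants:
        return CASLModelConstants(self.alpha, self.lambda_ml_per_g)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {k: clean(v) for k, v in dataclasses.asdict(self).items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        geo = d.pop("geometry", None)
        if geo is not None:
            geo = dict(geo)
            for key in ("matrix_size", "fov_mm", "b_values_s_per_mm2", "ir_inversion_times_ms"):
                if key in geo:
                    geo[key] = tuple(geo[key])
            geometry = AcquisitionGeometry(**geo)
        else:
            geometry = DEFAULT_GEOMETRY
        raw_groups = d.pop("groups", None)
        groups: List[GroupSpec] = []
        for g in raw_groups or []:
            g = dict(g)
            strain = g.pop("strain", "C57Bl/6")
            tissue_means = g.pop("tissue_means", None)
            lesion_fractions = g.pop("lesion_fractions", None)
            spec = default_group_spec(strain, **g)
            if tissue_means:
                from .phantom import TissueValues
                spec = replace(spec, tissue_means={
                    tp: TissueValues(**vals) for tp, vals in tissue_means.items()})
            if lesion_fractions:
                spec = replace(spec, lesion_fractions={
                    tp: {roi: tuple(ms) for roi, ms in rois.items()}
                    for tp, rois in lesion_fractions.items()})
            groups.append(spec)
        d.pop("timepoints", None)
        return cls(geometry=geometry, groups=tuple(groups), **d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (run location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def default_config(**overrides) -> PipelineConfig:
    """Two-strain, n = 8 per group, two-timepoint study configuration."""
    groups = overrides.pop("groups", None)
    if groups is None:
        group_kwargs = overrides.pop("group_kwargs", {})
        groups = (default_group_spec("C57Bl/6", **group_kwargs),
                  default_group_spec("Sv/129", **group_kwargs))
    return PipelineConfig(groups=tuple(groups), **overrides)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    config: PipelineConfig
    template: AtlasTemplate
    subjects: List[dict]
    probability_maps: Dict[Tuple[str, str], ProbabilityMap]
    group_mean_maps: Dict[Tuple[str, str], Dict[str, np.ndarray]]
    summaries: dict
    wilcoxon: dict
    artifacts: Dict[str, str] = field(default_factory=dict)

    def to_results_dict(self) -> dict:
        return {
            "software": {"name": "strokemri", "version": __version__},
            "config_hash": self.config.config_hash(),
            "master_seed": self.config.master_seed,
            "groups": [g.strain for g in self.config.groups],
            "subjects": self.subjects,
            "summaries": self.summaries,
            "wilcoxon": self.wilcoxon,
            "artifacts": self.artifacts,
        }


def _summary_dict(s: ROISummary) -> dict:
    return {"mean": s.mean, "sem": s.sem, "n": s.n,
            "per_subject": list(s.per_subject_values)}


def _wilcoxon_dict(r) -> dict:
    return {"W": r.statistic_w, "n_effective": r.n_effective,
            "p_two_sided": r.p_two_sided, "method": r.method,
            "all_zero": r.all_zero}


# ---------------------------------------------------------------------------
# per-subject analysis
# ---------------------------------------------------------------------------


def _fit_native_maps(raw, config: PipelineConfig, brain: np.ndarray) -> Dict[str, QuantitativeMap]:
    geo = raw.geometry
    t2 = fit_t2_map(raw.echo_train, geo.echo_times_ms, config.n_echoes_used, mask=brain)
    if config.t1_source == "fit":
        t1 = fit_t1_map(raw.ir_series, np.asarray(geo.ir_inversion_times_ms), mask=brain)
    else:
        values = np.where(brain, config.fixed_t1_ms, np.nan)
        t1 = QuantitativeMap(values, "ms", brain.copy())
    adc = compute_adc_map(raw.dwi_b0, raw.dwi_b800, geo.b_value_s_per_mm2, mask=brain)
    cbf = compute_cbf_map(raw.casl_control, raw.casl_label, t1,
                          config.casl_constants, mask=brain)
    return {"t2": t2, "t1": t1, "adc": adc, "cbf": cbf}


def _estimate_transforms(subject: SyntheticSubject, template: AtlasTemplate,
                         brains: Dict[str, np.ndarray],
                         native: Dict[str, Dict[str, QuantitativeMap]],
                         config: PipelineConfig) -> Dict[str, RigidTransform]:
    center = template.geometry.center_mm
    if config.registration == "identity":
        return {tp: RigidTransform.identity(center) for tp in config.timepoints}
    fixed = template.reference_intensity
    fixed_mask = template.brain_mask
    geo = template.geometry

    def reg_mask(tp: str) -> np.ndarray:
        # cost-function masking: the infarct is the dominant contrast
        # difference against the healthy template (and across timepoints),
        # and it is segmentable in native space before any registration
        seg = segment_infarct_t2(native[tp]["t2"], config.threshold_ms,
                                 brains[tp], direction=config.threshold_direction)
        if 0 < seg.mask.sum() < 0.5 * brains[tp].sum():
            return brains[tp] & ~seg.mask
        return brains[tp]

    masks = {tp: reg_mask(tp) for tp in config.timepoints}
    out: Dict[str, RigidTransform] = {}
    if config.registration == "direct":
        for tp in config.timepoints:
            res = register_rigid(subject.raw[tp].echo_train[..., 0], fixed,
                                 masks[tp], fixed_mask, geo, geo)
            out[tp] = res.transform
        return out
    # step-wise: intra-subject alignment to the first timepoint, then
    # first-timepoint -> template, composed.
    tp0 = config.timepoints[0]
    res0 = register_rigid(subject.raw[tp0].echo_train[..., 0], fixed,
                          masks[tp0], fixed_mask, geo, geo)
    out[tp0] = res0.transform
    for tp in config.timepoints[1:]:
        intra = register_rigid(subject.raw[tp].echo_train[..., 0],
                               subject.raw[tp0].echo_train[..., 0],
                               masks[tp], masks[tp0], geo, geo)
        out[tp] = res0.transform.compose(intra.transform)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """Execute the full simulate/analyze/summarize pipeline for one config."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir) if config.output_dir else None
    log_file_handler = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_file_handler = logging.FileHandler(out_dir / "run.log")
        log_file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(log_file_handler)
    if not config.groups:
        raise StageError("config", "at least one group must be configured")

    try:
        return _run(config, out_dir)
    finally:
        if log_file_handler is not None:
            logger.removeHandler(log_file_handler)
            log_file_handler.close()


def _run(config: PipelineConfig, out_dir: Optional[Path]) -> CohortResult:
    t_start = time.time()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t_start)

    stage("template")
    try:
        template = build_template(config.geometry)
    except Exception as exc:
        raise StageError("template", str(exc)) from exc

    artifacts: Dict[str, str] = {}
    if out_dir:
        artifacts["template_labels"] = str(save_nifti(
            template.labels, template.geometry, out_dir / "template_labels.nii",
            dtype=np.int16, description="atlas labels"))
        artifacts["template_reference"] = str(save_nifti(
            template.reference_intensity, template.geometry,
            out_dir / "template_reference.nii", description="reference intensity"))

    stage("simulate")
    cohorts: Dict[str, List[SyntheticSubject]] = {}
    try:
        for gi, gspec in enumerate(config.groups):
            cohorts[gspec.strain] = synthesize_cohort(
                gspec, template, config.master_seed, gi,
                casl_constants=config.casl_constants,
                timepoints=config.timepoints)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    subjects_out: List[dict] = []
    lesion_masks: Dict[Tuple[str, str], List[BinaryLesionMask]] = {}
    manual_masks: Dict[Tuple[str, str], List[BinaryLesionMask]] = {}
    atlas_maps_all: Dict[Tuple[str, str], Dict[str, List[QuantitativeMap]]] = {}
    for gspec in config.groups:
        for tp in config.timepoints:
            lesion_masks[(gspec.strain, tp)] = []
            manual_masks[(gspec.strain, tp)] = []
            atlas_maps_all[(gspec.strain, tp)] = {"t2": [], "adc": [], "cbf": []}

    vent = template.ventricle_mask

    for gspec in config.groups:
        for subject in cohorts[gspec.strain]:
            stage(f"analyze {subject.subject_id}")
            brains: Dict[str, np.ndarray] = {}
            native: Dict[str, Dict[str, QuantitativeMap]] = {}
            try:
                for tp in config.timepoints:
                    raw = subject.raw[tp]
                    if config.brain_extraction == "ground_truth":
                        brain = extract_brain(None, "ground_truth", raw.brain_mask).mask
                    else:
                        brain = extract_brain(raw.echo_train[..., 0], "automatic").mask
                    brains[tp] = brain
                    native[tp] = _fit_native_maps(raw, config, brain)
            except Exception as exc:
                raise StageError("map_fitting", f"{subject.subject_id}: {exc}") from exc

            try:
                transforms = _estimate_transforms(subject, template, brains, native, config)
            except Exception as exc:
                raise StageError("registration", f"{subject.subject_id}: {exc}") from exc

            record = {"subject_id": subject.subject_id, "strain": subject.strain,
                      "seed": subject.seed, "timepoints": {}}
            for tp in config.timepoints:
                try:
                    # threshold in native space, then carry the binary mask to
                    # atlas space by nearest-neighbour: interpolating the T2
                    # map across the sharp lesion boundary before
                    # thresholding would bias the boundary voxels
                    seg_native = segment_infarct_t2(
                        native[tp]["t2"], config.threshold_ms, brains[tp],
                        direction=config.threshold_direction,
                        timepoint=tp, subject_id=subject.subject_id)
                    amaps, amasks = to_atlas(native[tp], transforms[tp], template,
                                             subject.raw[tp].geometry,
                                             masks={"brain": brains[tp],
                                                    "lesion_auto": seg_native.mask})
                except Exception as exc:
                    raise StageError("to_atlas", f"{subject.subject_id}/{tp}: {exc}") from exc

                try:
                    seg = BinaryLesionMask(amasks["lesion_auto"], "t2_threshold",
                                           config.threshold_ms, tp, subject.subject_id)
                    seg = remove_csf(seg, vent)
                    manual = segment_manual_emulated(
                        subject.lesion, tp,
                        rater_error_voxels=config.rater_error_voxels,
                        seed=subject.seed, subject_id=subject.subject_id)
                    vol = volume_ratio(manual, template)
                except Exception as exc:
                    raise StageError("segmentation", f"{subject.subject_id}/{tp}: {exc}") from exc

                lesion_masks[(subject.strain, tp)].append(seg)
                manual_masks[(subject.strain, tp)].append(manual)
                for key in ("t2", "adc", "cbf"):
                    atlas_maps_all[(subject.strain, tp)][key].append(amaps[key])

                record["timepoints"][tp] = {
                    "transform": transforms[tp].to_dict(),
                    "true_misalignment": subject.misalignment[tp].to_dict(),
                    "volume_ratio": vol.ratio,
                    "lesion_voxels": vol.lesion_voxels,
                    "hemisphere_voxels": vol.hemisphere_voxels,
                    "auto_lesion_voxels": int(seg.mask.sum()),
                }
                if out_dir:
                    sdir = out_dir / "subjects" / subject.subject_id / tp
                    for key, qm in amaps.items():
                        save_nifti(np.nan_to_num(qm.values, nan=0.0), template.geometry,
                                   sdir / f"{key}_atlas.nii", description=qm.units)
                    save_nifti(seg.mask, template.geometry, sdir / "lesion_t2thresh.nii")
                    save_nifti(manual.mask, template.geometry, sdir / "lesion_manual.nii")
                    transforms[tp].to_json(sdir / "transform.json")
            subjects_out.append(record)

    stage("group_stats")
    summaries: dict = {}
    probability_maps: Dict[Tuple[str, str], ProbabilityMap] = {}
    group_mean_maps: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    roi_masks = {"cortex": template.cortex_mca_mask, "subcortex": template.subcortex_mask}

    try:
        for gspec in config.groups:
            strain = gspec.strain
            summaries[strain] = {}
            for tp in config.timepoints:
                masks = lesion_masks[(strain, tp)]
                pmap = probability_map(masks, strain, tp)
                probability_maps[(strain, tp)] = pmap
                entry = {}
                for roi, roi_mask in roi_masks.items():
                    entry[roi] = {
                        "probability_pct": _summary_dict(roi_probability(masks, roi_mask, roi)),
                        "cbf": _summary_dict(roi_mean_summary(
                            atlas_maps_all[(strain, tp)]["cbf"], roi_mask, roi)),
                        "adc": _summary_dict(roi_mean_summary(
                            atlas_maps_all[(strain, tp)]["adc"], roi_mask, roi)),
                    }
                ratios = [volume_ratio(m, template).ratio for m in manual_masks[(strain, tp)]]
                entry["volume_ratio"] = {
                    "mean": float(np.mean(ratios)),
                    "sem": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0,
                    "n": len(ratios),
                    "per_subject": [float(r) for r in ratios],
                }
                summaries[strain][tp] = entry
                with np.errstate(invalid="ignore"):
                    import warnings as _warnings
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore", RuntimeWarning)
                        group_mean_maps[(strain, tp)] = {
                            key: np.nanmean(
                                np.stack([m.masked() for m in atlas_maps_all[(strain, tp)][key]]),
                                axis=0)
                            for key in ("t2", "cbf", "adc")
                        }
                group_mean_maps[(strain, tp)]["probability"] = pmap.values
    except Exception as exc:
        raise StageError("group_stats", str(exc)) from exc

    stage("wilcoxon")
    wilcoxon: dict = {"roi_comparisons": {}, "volumetry_comparisons": {},
                      "probability_comparisons": {}}
    if len(config.groups) >= 2:
        s_a, s_b = config.groups[0].strain, config.groups[1].strain
        try:
            for tp in config.timepoints:
                for roi in ROIS:
                    for quant in ("cbf", "adc"):
                        xa = summaries[s_a][tp][roi][quant]["per_subject"]
                        xb = summaries[s_b][tp][roi][quant]["per_subject"]
                        key = f"{quant}_{roi}_{tp}"
                        wilcoxon["roi_comparisons"][key] = _wilcoxon_dict(
                            wilcoxon_signed_rank_exact(xa, xb))
                    pa = summaries[s_a][tp][roi]["probability_pct"]["per_subject"]
                    pb = summaries[s_b][tp][roi]["probability_pct"]["per_subject"]
                    wilcoxon["probability_comparisons"][f"{roi}_{tp}"] = _wilcoxon_dict(
                        wilcoxon_signed_rank_exact(pa, pb))
                ra = summaries[s_a][tp]["volume_ratio"]["per_subject"]
                rb = summaries[s_b][tp]["volume_ratio"]["per_subject"]
                wilcoxon["volumetry_comparisons"][tp] = _wilcoxon_dict(
                    wilcoxon_signed_rank_exact(ra, rb))
        except Exception as exc:
            raise StageError("wilcoxon", str(exc)) from exc

    result = CohortResult(
        config=config, template=template, subjects=subjects_out,
        probability_maps=probability_maps, group_mean_maps=group_mean_maps,
        summaries=summaries, wilcoxon=wilcoxon, artifacts=artifacts,
    )

    if out_dir:
        stage("write_results")
        for (strain, tp), pmap in probability_maps.items():
            key = f"probability_{strain.replace('/', '')}_{tp}"
            artifacts[key] = str(save_nifti(
                pmap.values, template.geometry,
                out_dir / f"{key}.nii", description="infarct probability"))
        save_json(config.to_dict(), out_dir / "resolved_config.json")
        save_json(result.to_results_dict(), out_dir / "results.json")
    stage("done")
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def render_reports(result: CohortResult, output_dir) -> Dict[str, str]:
    """Write color-coded map panels, the volume-ratio bar chart and the two
    group tables (infarct probabilities; CBF/ADC means). Purely
    presentational: every number comes from the CohortResult."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    strains = [g.strain for g in cfg.groups]
    tps = list(cfg.timepoints)
    mid = result.template.geometry.n_slices // 2
    files: Dict[str, str] = {}

    def panel(key, fname, cmap, vmin=None, vmax=None, title=""):
        fig, axes = plt.subplots(len(strains), len(tps),
                                 figsize=(3 * len(tps), 2.6 * len(strains)),
                                 squeeze=False)
        for i, s in enumerate(strains):
            for j, tp in enumerate(tps):
                img = result.group_mean_maps[(s, tp)][key][:, :, mid].T
                im = axes[i][j].imshow(img, cmap=cmap, vmin=vmin, vmax=vmax,
                                       origin="lower")
                axes[i][j].set_title(f"{s} {tp}", fontsize=9)
                axes[i][j].axis("off")
        fig.suptitle(title)
        fig.colorbar(im, ax=[ax for row in axes for ax in row], shrink=0.8)
        path = out / fname
        fig.savefig(path, dpi=110)
        plt.close(fig)
        files[fname] = str(path)

    panel("probability", "fig_probability_maps.png", "hot", 0.0, 1.0,
          "Group infarct probability")
    panel("t2", "fig_t2_maps.png", "viridis", title="Group mean T2 (ms)")
    panel("cbf", "fig_cbf_maps.png", "magma", title="Group mean CBF (mL/100g/min)")

    fig, ax = plt.subplots(figsize=(5, 3.5))
    width = 0.35
    xpos = np.arange(len(tps))
    for i, s in enumerate(strains):
        means = [result.summaries[s][tp]["volume_ratio"]["mean"] for tp in tps]
        sems = [result.summaries[s][tp]["volume_ratio"]["sem"] for tp in tps]
        ax.bar(xpos + i * width, means, width, yerr=sems, capsize=4, label=s)
    ax.set_xticks(xpos + width / 2)
    ax.set_xticklabels(tps)
    ax.set_ylabel("infarct / hemisphere volume ratio")
    ax.legend()
    fig.tight_layout()
    path = out / "fig_volume_ratios.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    files["fig_volume_ratios.png"] = str(path)

    def fmt(entry):
        return f"{entry['mean']:.1f} ± {entry['sem']:.1f}"

    rows = []
    for roi in ROIS:
        row = {"ROI": roi}
        for s in strains:
            for tp in tps:
                row[f"{s} {tp}"] = fmt(result.summaries[s][tp][roi]["probability_pct"])
        rows.append(row)
    p1 = out / "table1_infarct_probabilities.csv"
    pd.DataFrame(rows).to_csv(p1, index=False)
    files[p1.name] = str(p1)

    rows = []
    for quant, scale, unit in (("cbf", 1.0, "mL/100g/min"), ("adc", 1e4, "1e-4 mm^2/s")):
        for roi in ROIS:
            row = {"measure": quant.upper(), "units": unit, "ROI": roi}
            for s in strains:
                for tp in tps:
                    e = result.summaries[s][tp][roi][quant]
                    row[f"{s} {tp}"] = f"{e['mean'] * scale:.1f} ± {e['sem'] * scale:.1f}"
            rows.append(row)
    p2 = out / "table2_cbf_adc.csv"
    pd.DataFrame(rows).to_csv(p2, index=False)
    files[p2.name] = str(p2)

    vol_rows = []
    for rec in result.subjects:
        for tp, entry in rec["timepoints"].items():
            vol_rows.append({"subject": rec["subject_id"], "strain": rec["strain"],
                             "timepoint": tp, "method": "manual_emulated",
                             "lesion_voxels": entry["lesion_voxels"],
                             "hemisphere_voxels": entry["hemisphere_voxels"],
                             "ratio": entry["volume_ratio"]})
    pv = out / "volumetry.csv"
    pd.DataFrame(vol_rows).to_csv(pv, index=False)
    files[pv.name] = str(pv)
    return files
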