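"""Group-level statistics: probability maps, ROI summaries, exact Wilcoxon.

All summaries are mean +/- SEM (sample SD / sqrt(n)). The matched-pairs
Wilcoxon signed-rank test uses exact enumeration of all sign assignments
for small samples (n_eff <= 12) and a tie-corrected normal approximation
beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats as sps

from .lesion import BinaryLesionMask
from .maps import QuantitativeMap

__all__ = [
    "ProbabilityMap",
    "ROISummary",
    "WilcoxonResult",
    "probability_map",
    "roi_probability",
    "roi_mean",
    "roi_mean_summary",
    "wilcoxon_signed_rank_exact",
    "sem",
]

MaskLike = Union[BinaryLesionMask, np.ndarray]


def _as_mask_array(m: MaskLike) -> np.ndarray:
    if isinstance(m, BinaryLesionMask):
        return m.mask
    return np.asarray(m, dtype=bool)


@dataclass(frozen=True)
class ProbabilityMap:
    """Voxel-wise fraction of subjects whose lesion covers each voxel."""

    values: np.ndarray
    n_subjects: int
    group_label: str = ""
    timepoint: str = ""


@dataclass(frozen=True)
class ROISummary:
    roi_label: str
    per_subject_values: tuple
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic_w: float
    n_effective: int
    p_two_sided: float
    method: str  # "exact_enumeration" | "normal_approximation"
    all_zero: bool = False


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least 2 values")
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def probability_map(
    masks: Sequence[MaskLike],
    group_label: str = "",
    timepoint: str = "",
) -> ProbabilityMap:
    """Within-group infarct probability: voxel-wise mean of binary masks."""
    if len(masks) == 0:
        raise ValueError("probability map requires at least one mask")
    arrays = [_as_mask_array(m) for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all masks must share the atlas grid")
    values = np.mean(np.stack(arrays, axis=0).astype(float), axis=0)
    return ProbabilityMap(values=values, n_subjects=len(arrays),
                          group_label=group_label, timepoint=timepoint)


def roi_probability(masks: Sequence[MaskLike], roi_mask: np.ndarray,
                    roi_label: str = "roi") -> ROISummary:
    """Per-subject percent of the ROI infarcted, summarized mean +/- SEM.

    The group mean equals the ROI average of the probability map (an
    algebraic identity), so a cohort that fully infarcts the ROI reports
    exactly 100 +/- 0.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    vals = []
    for m in masks:
        a = _as_mask_array(m)
        if a.shape != roi.shape:
            raise ValueError("mask grid does not match the ROI")
        vals.append(100.0 * float((a & roi).sum()) / n_roi)
    v = np.asarray(vals)
    return ROISummary(roi_label=roi_label, per_subject_values=tuple(vals),
                      mean=float(v.mean()),
                      sem=sem(v) if v.size >= 2 else 0.0,
                      n=v.size)


def roi_mean(qmap: QuantitativeMap, roi_mask: np.ndarray) -> float:
    """Mean of a quantitative map over ROI ∩ validity for one subject."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != qmap.shape:
        raise ValueError("ROI grid does not match the map")
    sel = roi & qmap.validity_mask
    if not sel.any():
        raise ValueError("ROI does not overlap the map's validity mask")
    return float(qmap.values[sel].mean())


def roi_mean_summary(maps: Sequence[QuantitativeMap], roi_mask: np.ndarray,
                     roi_label: str = "roi") -> ROISummary:
    """Across-subject summary (mean +/- SEM) of per-subject ROI means."""
    vals = [roi_mean(m, roi_mask) for m in maps]
    v = np.asarray(vals)
    return ROISummary(roi_label=roi_label, per_subject_values=tuple(vals),
                      mean=float(v.mean()),
                      sem=sem(v) if v.size >= 2 else 0.0,
                      n=v.size)


def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p over all sign assignments of the (doubled) ranks.

    ``ranks2`` are mid-ranks times two, hence integers; enumeration of all
    2^n subsets is exact in integer arithmetic, and the two-sided p is
    min(1, 2 * min(P(W <= w), P(W >= w))) under the symmetric null.
    """
    n = ranks2.size
    total = 1 << n
    combos = np.arange(total, dtype=np.uint64)
    bits = (combos[:, None] >> np.arange(n, dtype=np.uint64)) & 1
    w_all = bits.astype(np.int64) @ ranks2.astype(np.int64)
    n_low = int(np.count_nonzero(w_all <= w2))
    n_high = int(np.count_nonzero(w_all >= w2))
    p = 2.0 * min(n_low, n_high) / total
    return min(1.0, p)


def wilcoxon_signed_rank_exact(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "discard",
    exact_max_n: int = 12,
) -> WilcoxonResult:
    """Matched-pairs Wilcoxon signed-rank test with an exact small-n null.

    Differences ``d = x - y``; zero differences are discarded (classical
    convention; ``zero_method='pratt'`` ranks them before discarding);
    ``|d|`` is ranked with mid-ranks for ties; W is the sum of ranks of
    positive differences. For n_eff <= ``exact_max_n`` the two-sided p comes
    from exact enumeration of all sign assignments; beyond that from a
    tie-corrected normal approximation. All differences zero returns
    p = 1 with W reported as 0 and an ``all_zero`` flag.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xv.size < 1:
        raise ValueError("need at least one pair")
    d = xv - yv

    if zero_method == "discard":
        d_eff = d[d != 0]
        ranks = sps.rankdata(np.abs(d_eff)) if d_eff.size else np.array([])
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        keep = d != 0
        d_eff = d[keep]
        ranks = ranks_all[keep]
    else:
        raise ValueError("zero_method must be 'discard' or 'pratt'")

    n_eff = int(d_eff.size)
    if n_eff == 0:
        return WilcoxonResult(statistic_w=0.0, n_effective=0, p_two_sided=1.0,
                              method="exact_enumeration", all_zero=True)

    w = float(ranks[d_eff > 0].sum())
    ranks2 = np.rint(2.0 * ranks).astype(np.int64)
    w2 = int(round(2.0 * w))

    if n_eff <= exact_max_n:
        p = _exact_two_sided_p(ranks2, w2)
        return WilcoxonResult(statistic_w=w, n_effective=n_eff,
                              p_two_sided=p, method="exact_enumeration")

    mu = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0  # tie-aware: Var(W) = sum r_i^2 / 4
    if var == 0:
        return WilcoxonResult(statistic_w=w, n_effective=n_eff, p_two_sided=1.0,
                              method="normal_approximation")
    z = (w - mu) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(statistic_w=w, n_effective=n_eff,
                          p_two_sided=p, method="normal_approximation")
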