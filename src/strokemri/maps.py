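"""Voxel-wise quantitative parameter mapping.

Implements the four maps of the multimodal stroke protocol:

* T2 relaxometry: per-voxel monoexponential fit ``S(TE) = S0 exp(-TE/T2)``
  to the first 20 echoes of a CPMG train, log-linear initialization followed
  by damped (Levenberg-Marquardt) nonlinear least squares.
* T1 relaxometry: three-parameter magnitude inversion-recovery fit
  ``|S0 (1 - B exp(-TI/T1))|`` with polarity restoration.
* ADC: two-point diffusion map ``ADC = -(1/b) ln(S_b / S_0)``; at
  b = 800 s/mm^2 the coefficient is exactly -0.00125.
* CBF: single-compartment continuous-ASL quantification
  ``CBF = 6000 * (lambda / T1[s]) * (S_ctrl - S_lbl) / (2 alpha S_ctrl)``
  in mL/100 g/min, with inversion efficiency alpha = 0.7 and blood-brain
  partition coefficient lambda = 0.95 mL/g by default.

Flagged (negative / failed) voxels are preserved, never clamped: masking is
a reporting-layer decision and clamping would bias group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = [
    "QuantitativeMap",
    "CASLModelConstants",
    "fit_t2_map",
    "fit_t1_map",
    "compute_adc_map",
    "compute_cbf_map",
]

T2_UNITS = "ms"
T1_UNITS = "ms"
ADC_UNITS = "mm^2/s"
CBF_UNITS = "mL/100g/min"


@dataclass
class QuantitativeMap:
    """A voxel-wise parametric image with units and a validity mask."""

    values: np.ndarray
    units: str
    validity_mask: np.ndarray
    residual_norm: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask must share one grid")
        if not np.all(np.isfinite(self.values[self.validity_mask])):
            raise ValueError("values must be finite on the validity mask")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    def masked(self, fill=np.nan) -> np.ndarray:
        out = np.full_like(self.values, fill, dtype=float)
        out[self.validity_mask] = self.values[self.validity_mask]
        return out


@dataclass(frozen=True)
class CASLModelConstants:
    """Constants of the single-compartment CASL quantification."""

    alpha: float = 0.7  # labeling inversion efficiency, dimensionless
    lambda_ml_per_g: float = 0.95  # brain-blood partition coefficient of water

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.lambda_ml_per_g <= 0:
            raise ValueError("lambda must be positive")


# ---------------------------------------------------------------------------
# batched Levenberg-Marquardt
# ---------------------------------------------------------------------------


def _lm_fit(
    model_jac: Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray]],
    p0: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    rtol: float = 1e-8,
    lam0: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss-Newton over a batch of independent small problems.

    ``p0``: (n, k) initial parameters; ``y``: (n, m) data;
    ``model_jac(p) -> (f (n, m), J (n, m, k))``.
    Returns (parameters, converged flags, residual norms). Each voxel keeps
    its own damping factor; steps that do not reduce the cost are rejected.
    """
    p = np.array(p0, dtype=float)
    n, k = p.shape
    lam = np.full(n, lam0)
    # voxels that wander into overflow territory produce inf costs, get
    # their steps rejected and end up flagged invalid; silence the noise
    with np.errstate(over="ignore", invalid="ignore"):
        f, _ = model_jac(p)
        cost = np.sum((f - y) ** 2, axis=1)
    converged = np.zeros(n, dtype=bool)
    eye = np.eye(k)

    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_iter):
            if converged.all():
                break
            f, jac = model_jac(p)
            r = y - f
            g = np.einsum("nmk,nm->nk", jac, r)
            h = np.einsum("nmk,nml->nkl", jac, jac)
            damp = h + lam[:, None, None] * (
                np.abs(np.diagonal(h, axis1=1, axis2=2))[:, :, None] * eye + 1e-12 * eye)
            damp = np.where(np.isfinite(damp), damp, 1.0)
            g = np.where(np.isfinite(g), g, 0.0)
            try:
                step = np.linalg.solve(damp, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.stack([np.linalg.lstsq(a_i, g_i, rcond=None)[0]
                                 for a_i, g_i in zip(damp, g)])
            p_new = p + step
            f_new, _ = model_jac(p_new)
            cost_new = np.sum((f_new - y) ** 2, axis=1)
            improved = (cost_new <= cost) & ~converged
            rel_drop = np.where(cost > 0, (cost - cost_new) / np.maximum(cost, 1e-300), 0.0)
            newly_conv = improved & ((rel_drop < rtol) | (cost_new < 1e-300))
            p[improved] = p_new[improved]
            cost[improved] = cost_new[improved]
            lam[improved] = np.maximum(lam[improved] * 0.3, 1e-12)
            rejected = ~improved & ~converged
            lam[rejected] = np.minimum(lam[rejected] * 10.0, 1e10)
            converged |= newly_conv
            # voxels whose damping exploded are stuck; declare them done
            # (parameter sanity checks decide validity afterwards)
            converged |= lam >= 1e10

    resnorm = np.sqrt(cost)
    return p, converged, resnorm


# ---------------------------------------------------------------------------
# T2 relaxometry
# ---------------------------------------------------------------------------


def _loglinear_exp_init(te: np.ndarray, sig: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Weighted log-linear estimate of (S0, R2) for S = S0 exp(-TE R2).

    Weights proportional to the squared signal approximate uniform noise in
    signal space and keep the estimator stable for decayed late echoes.
    """
    s = np.maximum(sig, 1e-300)
    w = s**2
    ly = np.log(s)
    w_sum = w.sum(axis=1)
    te_b = np.broadcast_to(te, s.shape)
    te_mean = (w * te_b).sum(axis=1) / w_sum
    ly_mean = (w * ly).sum(axis=1) / w_sum
    dte = te_b - te_mean[:, None]
    cov = (w * dte * (ly - ly_mean[:, None])).sum(axis=1)
    var = (w * dte**2).sum(axis=1)
    slope = np.where(var > 0, cov / np.maximum(var, 1e-300), 0.0)
    r2 = np.maximum(-slope, 1e-8)
    s0 = np.exp(ly_mean + r2 * te_mean)
    return s0, r2


def fit_t2_map(
    echo_train: np.ndarray,
    echo_times_ms: np.ndarray,
    n_echoes_used: int = 20,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 100,
    rtol: float = 1e-8,
) -> QuantitativeMap:
    """Monoexponential T2 fit of the first ``n_echoes_used`` echoes.

    Voxels with any non-positive signal among the used echoes, or whose fit
    fails to converge, are flagged invalid rather than silently filled.
    """
    data = np.asarray(echo_train, dtype=float)
    if data.ndim != 4:
        raise ValueError("echo_train must be 4-D (space x echoes)")
    te = np.asarray(echo_times_ms, dtype=float)
    if n_echoes_used < 3:
        raise ValueError("need at least 3 echoes for a 2-parameter fit")
    if te.size < n_echoes_used or data.shape[-1] < n_echoes_used:
        raise ValueError("fewer echoes than n_echoes_used")
    if np.any(np.diff(te[:n_echoes_used]) <= 0):
        raise ValueError("echo times must be strictly increasing")
    spatial = data.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask grid does not match echo_train grid")

    te_used = te[:n_echoes_used]
    sig = data[..., :n_echoes_used].reshape(-1, n_echoes_used)
    flat_mask = mask.reshape(-1)
    positive = np.all(sig > 0, axis=1)
    fit_idx = np.flatnonzero(flat_mask & positive)

    t2 = np.full(sig.shape[0], np.nan)
    valid = np.zeros(sig.shape[0], dtype=bool)
    resnorm = np.full(sig.shape[0], np.nan)

    if fit_idx.size:
        y = sig[fit_idx]
        s0_0, r2_0 = _loglinear_exp_init(te_used, y)
        p0 = np.stack([s0_0, r2_0], axis=1)

        def model_jac(p):
            s0, r2 = p[:, 0], p[:, 1]
            e = np.exp(-te_used[None, :] * r2[:, None])
            f = s0[:, None] * e
            jac = np.stack([e, -f * te_used[None, :]], axis=2)
            return f, jac

        p, conv, rn = _lm_fit(model_jac, p0, y, max_iter=max_iter, rtol=rtol)
        ok = conv & (p[:, 0] > 0) & (p[:, 1] > 0)
        t2[fit_idx] = np.where(p[:, 1] > 0, 1.0 / np.maximum(p[:, 1], 1e-300), np.nan)
        valid[fit_idx] = ok
        resnorm[fit_idx] = rn

    values = t2.reshape(spatial)
    values[~valid.reshape(spatial)] = np.nan
    return QuantitativeMap(values, T2_UNITS, valid.reshape(spatial),
                           residual_norm=resnorm.reshape(spatial),
                           diagnostics={"n_echoes_used": n_echoes_used})


# ---------------------------------------------------------------------------
# T1 inversion recovery
# ---------------------------------------------------------------------------


def fit_t1_map(
    ir_series: np.ndarray,
    inversion_times_ms: np.ndarray,
    mask: Optional[np.ndarray] = None,
    max_iter: int = 100,
    rtol: float = 1e-10,
) -> QuantitativeMap:
    """Three-parameter magnitude inversion-recovery T1 fit.

    The signed model ``S0 (1 - B exp(-TI/T1))`` is fitted after polarity
    restoration: both candidate sign patterns around the signal minimum are
    fitted and the lower-residual solution kept per voxel.
    """
    data = np.asarray(ir_series, dtype=float)
    if data.ndim != 4:
        raise ValueError("ir_series must be 4-D (space x inversion times)")
    ti = np.asarray(inversion_times_ms, dtype=float)
    if ti.size < 3 or data.shape[-1] != ti.size:
        raise ValueError("need >= 3 inversion times matching the series length")
    spatial = data.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask grid does not match ir_series grid")

    m = ti.size
    sig = data.reshape(-1, m)
    flat_mask = mask.reshape(-1)
    dyn = sig.max(axis=1) - sig.min(axis=1)
    usable = flat_mask & (sig.max(axis=1) > 0) & (dyn > 1e-9 * np.maximum(sig.max(axis=1), 1e-300))
    fit_idx = np.flatnonzero(usable)

    t1 = np.full(sig.shape[0], np.nan)
    valid = np.zeros(sig.shape[0], dtype=bool)
    resnorm = np.full(sig.shape[0], np.nan)

    if fit_idx.size:
        y_mag = sig[fit_idx]
        imin = np.argmin(y_mag, axis=1)

        def fit_candidate(include_min_negative: bool):
            flip = np.arange(m)[None, :] < imin[:, None]
            if include_min_negative:
                flip = np.arange(m)[None, :] <= imin[:, None]
            y = np.where(flip, -y_mag, y_mag)
            s0_0 = np.maximum(y[:, -1], 1e-6)
            b_0 = np.clip(1.0 - y[:, 0] / s0_0, 0.5, 3.0)
            ti_null = np.maximum(ti[imin], ti[0])
            r1_0 = np.log(np.maximum(b_0, 1.01)) / ti_null

            p0 = np.stack([s0_0, b_0, r1_0], axis=1)

            def model_jac(p):
                s0, b, r1 = p[:, 0], p[:, 1], p[:, 2]
                e = np.exp(-ti[None, :] * r1[:, None])
                f = s0[:, None] * (1.0 - b[:, None] * e)
                d_s0 = 1.0 - b[:, None] * e
                d_b = -s0[:, None] * e
                d_r1 = s0[:, None] * b[:, None] * e * ti[None, :]
                return f, np.stack([d_s0, d_b, d_r1], axis=2)

            p, conv, rn = _lm_fit(model_jac, p0, y, max_iter=max_iter, rtol=rtol)
            return p, conv, rn

        p_a, conv_a, rn_a = fit_candidate(False)
        p_b, conv_b, rn_b = fit_candidate(True)
        pick_b = rn_b < rn_a
        p = np.where(pick_b[:, None], p_b, p_a)
        conv = np.where(pick_b, conv_b, conv_a)
        rn = np.where(pick_b, rn_b, rn_a)

        ok = conv & (p[:, 0] > 0) & (p[:, 2] > 0)
        t1[fit_idx] = np.where(p[:, 2] > 0, 1.0 / np.maximum(p[:, 2], 1e-300), np.nan)
        valid[fit_idx] = ok
        resnorm[fit_idx] = rn

    values = t1.reshape(spatial)
    values[~valid.reshape(spatial)] = np.nan
    return QuantitativeMap(values, T1_UNITS, valid.reshape(spatial),
                           residual_norm=resnorm.reshape(spatial))


# ---------------------------------------------------------------------------
# ADC
# ---------------------------------------------------------------------------


def compute_adc_map(
    dwi_b0: np.ndarray,
    dwi_b800: np.ndarray,
    b_s_per_mm2: float = 800.0,
    mask: Optional[np.ndarray] = None,
) -> QuantitativeMap:
    """Two-point ADC map: ``ADC = -(1/b) ln(S_b / S_0)`` in mm^2/s."""
    s0 = np.asarray(dwi_b0, dtype=float)
    sb = np.asarray(dwi_b800, dtype=float)
    if s0.shape != sb.shape:
        raise ValueError("b=0 and diffusion-weighted volumes must share one grid")
    if b_s_per_mm2 <= 0:
        raise ValueError("b must be positive")
    if mask is None:
        mask = np.ones(s0.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != s0.shape:
        raise ValueError("mask grid mismatch")

    valid = mask & (s0 > 0) & (sb > 0)
    values = np.full(s0.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[valid] = -np.log(sb[valid] / s0[valid]) / b_s_per_mm2
    negative = valid & (values < 0)
    return QuantitativeMap(values, ADC_UNITS, valid,
                           diagnostics={"b_s_per_mm2": float(b_s_per_mm2),
                                        "n_negative": int(negative.sum()),
                                        "negative_mask": negative})


# ---------------------------------------------------------------------------
# CASL CBF
# ---------------------------------------------------------------------------


def compute_cbf_map(
    casl_control: np.ndarray,
    casl_label: np.ndarray,
    t1_map: QuantitativeMap,
    constants: CASLModelConstants = CASLModelConstants(),
    mask: Optional[np.ndarray] = None,
) -> QuantitativeMap:
    """Single-compartment CASL CBF map in mL/100 g/min.

    ``CBF = 6000 * (lambda / T1[s]) * (S_ctrl - S_lbl) / (2 alpha S_ctrl)``;
    the factor 6000 converts mL/g/s to mL/100 g/min.
    """
    ctrl = np.asarray(casl_control, dtype=float)
    lbl = np.asarray(casl_label, dtype=float)
    if ctrl.shape != lbl.shape or ctrl.shape != t1_map.shape:
        raise ValueError("control, label and T1 volumes must share one grid")
    if mask is None:
        mask = np.ones(ctrl.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ctrl.shape:
        raise ValueError("mask grid mismatch")

    t1_ms = t1_map.values
    valid = mask & (ctrl > 0) & t1_map.validity_mask & (t1_ms > 0)
    values = np.full(ctrl.shape, np.nan)
    t1_s = t1_ms[valid] / 1000.0
    values[valid] = (
        6000.0
        * (constants.lambda_ml_per_g / t1_s)
        * (ctrl[valid] - lbl[valid])
        / (2.0 * constants.alpha * ctrl[valid])
    )
    negative = valid & (values < 0)
    return QuantitativeMap(values, CBF_UNITS, valid,
                           diagnostics={"alpha": constants.alpha,
                                        "lambda_ml_per_g": constants.lambda_ml_per_g,
                                        "n_negative": int(negative.sum()),
                                        "negative_mask": negative})
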