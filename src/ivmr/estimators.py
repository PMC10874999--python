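"""Causal-effect estimators for harmonized instrument sets.

All estimators consume :class:`~ivmr.harmonize.HarmonizedInstrument`
collections and return :class:`MRResult`.  The inverse-variance-weighted
(IVW) estimator pools per-SNP Wald ratios with weights
``w_j = (beta_exp_j / se_out_j)^2`` (equivalently a weighted regression of
outcome on exposure effects through the origin); its multiplicative
random-effects variant inflates the fixed-effects SE by
``max(1, sqrt(Q / (k - 1)))`` and never deflates it.  MR-Egger adds an
intercept — a directional-pleiotropy estimate — after orienting every
instrument to a non-negative exposure effect.  The weighted median
interpolates the inverse-variance-weighted cumulative distribution of
ratio estimates at 50% and bootstraps its SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedInstrument

#: 97.5% normal quantile fixed for all 95% confidence intervals
Z95 = 1.959964


@dataclass
class MRResult:
    """One method's causal estimate on the log-odds and odds-ratio scales."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    extra: dict = field(default_factory=dict)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into OR with a 95% Wald CI."""
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def _two_sided_normal_p(beta: float, se: float) -> float:
    if se > 0:
        return max(float(np.finfo(float).tiny), 2.0 * stats.norm.sf(abs(beta / se)))
    return 1.0 if beta == 0 else float(np.finfo(float).tiny)


def _two_sided_t_p(stat_over_se: float, df: int) -> float:
    return max(float(np.finfo(float).tiny), 2.0 * stats.t.sf(abs(stat_over_se), df))


def _result(method: str, n_snp: int, beta: float, se: float, pval: float, **extra) -> MRResult:
    or_, lo, hi = to_odds_ratio(beta, se)
    return MRResult(method, n_snp, float(beta), float(se), float(pval), or_, lo, hi, extra)


def _arrays(insts: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    sx = np.array([i.se_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: HarmonizedInstrument) -> MRResult:
    """Single-SNP ratio estimate beta_out/beta_exp with first-order SE."""
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.snp_id}: beta_exp is zero, Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    pval = _two_sided_normal_p(beta, se)
    return _result("wald", 1, beta, se, pval, snp_id=inst.snp_id)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Pooled estimate, fixed-effects SE and Cochran's Q on ratio scale."""
    w = (bx / sy) ** 2
    theta = by / bx
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q


def ivw(insts: Sequence[HarmonizedInstrument], model: str = "random") -> MRResult:
    """Inverse-variance-weighted estimate, fixed or multiplicative random effects."""
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    k = len(insts)
    if k == 0:
        raise ValueError("IVW requires at least one instrument")
    if k == 1 and model == "random":
        warnings.warn("random-effects IVW needs >= 2 instruments; falling back to fixed", stacklevel=2)
        model = "fixed"
    bx, _, by, sy = _arrays(insts)
    if np.any(bx == 0):
        raise ValueError("IVW requires nonzero exposure effects for every instrument")
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    else:
        se = se_fixed
    pval = _two_sided_normal_p(beta, se)
    return _result(f"ivw_{'fe' if model == 'fixed' else 're'}", k, beta, se, pval, q=q)


def egger(insts: Sequence[HarmonizedInstrument]) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Instruments are internally oriented so exposure effects are
    non-negative (stored instruments are never mutated).  Slope and
    intercept SEs use a multiplicative overdispersion factor floored at 1;
    p-values come from t with ``k - 2`` degrees of freedom.
    """
    k = len(insts)
    if k < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {k}")
    bx, _, by, sy = _arrays(insts)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=1.0 / sy**2).fit()
    scale = max(1.0, float(fit.scale))  # fit.scale = weighted RSS / (k - 2)
    cov = scale * np.asarray(fit.normalized_cov_params)
    intercept, slope = fit.params
    se_intercept, se_slope = np.sqrt(np.diag(cov))
    df = k - 2
    p_slope = _two_sided_t_p(slope / se_slope, df) if se_slope > 0 else (1.0 if slope == 0 else float(np.finfo(float).tiny))
    p_intercept = _two_sided_t_p(intercept / se_intercept, df) if se_intercept > 0 else (1.0 if intercept == 0 else float(np.finfo(float).tiny))
    return _result(
        "egger",
        k,
        slope,
        se_slope,
        p_slope,
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_intercept),
        egger_intercept_p=float(p_intercept),
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratio estimates.

    With weights normalized to sum 1 and ratios sorted, the cumulative
    midpoint of ratio j is ``s_j = sum_{i<=j} w_(i) - w_(j)/2``; the
    estimate interpolates ratios against s at s = 1/2.
    """
    order = np.argsort(ratios)
    theta = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, theta))


def weighted_median(
    insts: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    *,
    seed: int,
) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap SE.

    Each bootstrap replicate perturbs every instrument's exposure and
    outcome effect by independent normal noise at their reported SEs and
    recomputes the weighted median; the estimate's SE is the standard
    deviation over replicates.
    """
    k = len(insts)
    if k < 3:
        raise ValueError(f"weighted median requires at least 3 instruments, got {k}")
    bx, sx, by, sy = _arrays(insts)
    if np.any(bx == 0):
        raise ValueError("weighted median requires nonzero exposure effects")
    beta = weighted_median_point(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.normal(0.0, sx)
        by_b = by + rng.normal(0.0, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        boot[b] = weighted_median_point(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(np.std(boot, ddof=1))
    pval = _two_sided_normal_p(beta, se)
    return _result("weighted_median", k, beta, se, pval, n_boot=n_boot, seed=seed)
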