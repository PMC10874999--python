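"""Heterogeneity, pleiotropy and robustness diagnostics.

Covers Cochran's Q on the ratio scale, the simulation-based residual-sum
outlier machinery (global test, per-SNP outlier test with Bonferroni
adjustment, outlier-corrected re-estimate, distortion test), leave-one-out
re-estimation and funnel-plot data.  Monte-Carlo p-values use the
``(1 + k) / (n + 1)`` estimator so they can never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, _arrays, _ivw_core, egger, ivw, wald_ratio
from .harmonize import HarmonizedInstrument


def cochran_q(insts: Sequence[HarmonizedInstrument]) -> tuple[float, int, float]:
    """Cochran's Q against the fixed-effects IVW estimate.

    Returns ``(q, df, p)`` with ``df = k - 1`` and the upper-tail
    chi-square p-value.
    """
    k = len(insts)
    if k < 2:
        raise ValueError(f"Cochran's Q requires at least 2 instruments, got {k}")
    bx, _, by, sy = _arrays(insts)
    _, _, q = _ivw_core(bx, by, sy)
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_estimates(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Fixed-effects IVW excluding each instrument in turn (vectorized)."""
    w = (bx / sy) ** 2
    theta = by / bx
    num, den = np.sum(w * theta), np.sum(w)
    return (num - w * theta) / (den - w)


@dataclass
class PressoResult:
    """Global, outlier, corrected and distortion outputs of the RSS test."""

    global_rss: float
    global_p: float
    outliers: list[tuple[str, float]] = field(default_factory=list)  # (snp_id, adjusted p)
    corrected: MRResult | None = None
    distortion_p: float | None = None
    n_sim: int = 0
    seed: int | None = None

    @property
    def outlier_ids(self) -> list[str]:
        return [s for s, _ in self.outliers]


def mr_presso(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    signif_threshold: float = 0.05,
    *,
    seed: int,
) -> PressoResult:
    """Residual-sum-of-squares outlier test with parametric simulation.

    Expected outcome effects come from leave-one-out IVW fits; the
    observed RSS is compared with ``n_sim`` datasets simulated under the
    no-outlier model (outcome effects drawn around their leave-one-out
    predictions, exposure effects around their observed values).  Per-SNP
    residual contributions give Bonferroni-adjusted outlier p-values; when
    the global test is significant, the IVW estimate is re-run without the
    flagged SNPs and a distortion p-value contrasts the shift against
    random same-size removals.
    """
    k = len(insts)
    if k < 4:
        raise ValueError(f"the outlier test requires at least 4 instruments, got {k}")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(insts)

    theta_loo = _loo_estimates(bx, by, sy)
    resid_obs = (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    # simulate under the no-outlier model, recomputing LOO fits per dataset
    bx_sim = bx + rng.normal(0.0, sx, size=(n_sim, k))
    by_sim = theta_loo * bx + rng.normal(0.0, sy, size=(n_sim, k))
    w_sim = (bx_sim / sy) ** 2
    theta_sim = by_sim / np.where(bx_sim == 0, np.finfo(float).tiny, bx_sim)
    num = np.sum(w_sim * theta_sim, axis=1, keepdims=True)
    den = np.sum(w_sim, axis=1, keepdims=True)
    theta_loo_sim = (num - w_sim * theta_sim) / (den - w_sim)
    resid_sim = (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_raw_p = np.mean(resid_sim >= resid_obs, axis=0)
    outlier_adj_p = np.minimum(1.0, outlier_raw_p * k)
    flagged = [
        (insts[j].snp_id, float(outlier_adj_p[j]))
        for j in range(k)
        if outlier_adj_p[j] < signif_threshold
    ]

    result = PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outliers=flagged,
        n_sim=n_sim,
        seed=seed,
    )

    if flagged and global_p < signif_threshold:
        flagged_ids = {s for s, _ in flagged}
        keep = [i for i in insts if i.snp_id not in flagged_ids]
        if len(keep) >= 2:
            result.corrected = ivw(keep, model="random")
            full = ivw(list(insts), model="random")
            d_obs = result.corrected.beta - full.beta
            n_flag = len(flagged_ids)
            d_null = np.empty(n_sim)
            idx = np.arange(k)
            for b in range(n_sim):
                drop = rng.choice(idx, size=n_flag, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                beta_b, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
                d_null[b] = beta_b - full.beta
            result.distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
        else:
            warnings.warn("outlier removal left fewer than 2 instruments; corrected estimate skipped")
    return result


def leave_one_out(insts: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Random-effects IVW after excluding each instrument in turn."""
    k = len(insts)
    if k < 2:
        raise ValueError(f"leave-one-out requires at least 2 instruments, got {k}")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k=2 rows degrade to single-SNP fixed fits
        for j in range(k):
            subset = [inst for i, inst in enumerate(insts) if i != j]
            res = ivw(subset, model="random")
            rows.append(
                {"excluded_snp": insts[j].snp_id, "beta": res.beta, "se": res.se, "pval": res.pval}
            )
    return pd.DataFrame(rows, columns=["excluded_snp", "beta", "se", "pval"])


def funnel_data(insts: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-instrument ratio estimate and its precision (1/SE) for funnel plots."""
    rows = []
    for inst in insts:
        res = wald_ratio(inst)
        rows.append({"snp_id": inst.snp_id, "ratio": res.beta, "precision": 1.0 / res.se})
    return pd.DataFrame(rows, columns=["snp_id", "ratio", "precision"])


@dataclass
class SensitivityReport:
    """Bundle of all robustness diagnostics for one instrument set."""

    q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: PressoResult | None
    loo: pd.DataFrame
    funnel: pd.DataFrame


def sensitivity_report(
    insts: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    signif_threshold: float = 0.05,
    *,
    seed: int,
) -> SensitivityReport:
    """Run every diagnostic that the instrument count permits."""
    q, q_df, q_p = cochran_q(insts)
    egger_res = egger(insts)
    presso = mr_presso(insts, n_sim=n_sim, signif_threshold=signif_threshold, seed=seed) if len(insts) >= 4 else None
    return SensitivityReport(
        q=q,
        q_df=q_df,
        q_p=q_p,
        egger_intercept=egger_res.extra["egger_intercept"],
        egger_intercept_se=egger_res.extra["egger_intercept_se"],
        egger_intercept_p=egger_res.extra["egger_intercept_p"],
        presso=presso,
        loo=leave_one_out(insts),
        funnel=funnel_data(insts),
    )
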