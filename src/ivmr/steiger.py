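"""Directionality test: do instruments explain more variance in the
exposure than in the outcome?

Per-SNP variance explained defaults to ``r2 = F / (F + n - 2)`` with
``F = beta^2 / se^2``, which needs no allele frequency and applies to the
observed scale of binary traits; for continuous traits with known
frequencies the standardized form ``2 * eaf * (1 - eaf) * beta^2`` can be
selected.  The two multiple correlations are compared with a two-sample
Fisher-z test, appropriate when exposure and outcome GWAS come from
non-overlapping samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument


@dataclass
class SteigerResult:
    """Summed variance explained on each side and the direction verdict."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_p: float


def snp_r2(beta: float, se: float, n: float, eaf: float | None = None, method: str = "f") -> float:
    """Variance in a trait explained by one SNP.

    ``method="f"`` uses ``F / (F + n - 2)``; ``method="eaf"`` uses the
    standardized-trait form ``2 * eaf * (1 - eaf) * beta^2`` and requires
    a frequency.
    """
    if n is None or n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if method == "f":
        f = (beta / se) ** 2
        return f / (f + n - 2)
    if method == "eaf":
        if eaf is None:
            raise ValueError("method 'eaf' requires an allele frequency")
        return 2.0 * eaf * (1.0 - eaf) * beta**2
    raise ValueError(f"unknown r2 method {method!r}")


def steiger_test(
    insts: Sequence[HarmonizedInstrument],
    n_exp: float,
    n_out: float,
    method: str = "f",
) -> SteigerResult:
    """Compare instrument-explained variance in exposure vs outcome.

    Sums per-SNP r2 on each side, then tests the difference of the two
    multiple correlations via Fisher's z transform of ``sqrt(r2)`` scaled
    by ``sqrt(1/(n_exp - 3) + 1/(n_out - 3))``.
    """
    if not insts:
        raise ValueError("Steiger test requires at least one instrument")
    if n_exp is None or n_out is None:
        raise ValueError("sample sizes unknown: set n_default on both datasets or pass n_exp/n_out")
    cap = 1.0 - 1e-12  # summed r2 is an approximation; keep atanh finite
    r2_exp = min(cap, sum(snp_r2(i.beta_exp, i.se_exp, n_exp, i.eaf_exp, method) for i in insts))
    r2_out = min(cap, sum(snp_r2(i.beta_out, i.se_out, n_out, i.eaf_out, method) for i in insts))
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    z = (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=float(r2_exp),
        r2_outcome=float(r2_out),
        correct_direction=bool(r2_exp > r2_out),
        steiger_p=p,
    )
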