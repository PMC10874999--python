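"""Synthetic paired GWAS summary statistics with known ground truth.

The generator follows a linear instrumental-variable model: each SNP j
has a true exposure effect ``gamma_j``, an optional direct (pleiotropic)
outcome effect ``alpha_j``, and a true outcome effect
``Gamma_j = theta * gamma_j + alpha_j`` where ``theta`` is the causal
effect.  Standard errors follow the usual summary-statistic approximation
``se = 1 / sqrt(2 * maf * (1 - maf) * n)`` and observed effects are drawn
normally around the truth.  Harmonization hazards (allele swaps, strand
flips, palindromic variants, duplicate rows) can be planted so the
cleaning stages are testable, and planted outliers shift the outcome
effect by a chosen number of its SEs.

All randomness descends from a single master seed through named
sub-streams, so the same configuration always writes byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import COMPLEMENT, HarmonizedInstrument, harmonize_datasets
from .sumstats import SummaryDataset, SummaryStatRecord, dedup_records

#: exposure/outcome GWAS sizes used as defaults (UK-Biobank-scale exposure,
#: FinnGen-scale outcome)
DEFAULT_N_EXP = 337_159
DEFAULT_N_OUT = 216_362

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic two-sample study."""

    n_snp: int = 80
    theta: float = 0.0
    gamma_mean: float = 0.04
    gamma_sd: float = 0.012
    gamma_fixed: Sequence[float] | None = None
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: float = DEFAULT_N_EXP
    n_out: float = DEFAULT_N_OUT
    maf_range: tuple[float, float] = (0.05, 0.5)
    outlier_count: int = 0
    outlier_offset: float = 0.0  # in units of the SNP's outcome SE
    swap_fraction: float = 0.0
    flip_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    reverse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("swap_fraction", "flip_fraction", "palindromic_fraction", "duplicate_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.outlier_count > self.n_snp:
            raise ValueError("more planted outliers than SNPs")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")


@dataclass
class SimulationTruth:
    """Ground truth recorded before observation noise and allele edits."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_ids: list[str] = field(default_factory=list)
    palindromic_ids: list[str] = field(default_factory=list)
    seed: int = 0


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Documented preset configurations.

    ``null``: no causal effect, no pleiotropy (type-I calibration).
    ``causal``: theta = 0.5 with 80 strong instruments (recovery/coverage).
    ``directional_pleiotropy``: no causal effect, directional alpha with
    mean 0.01 and sd 0.005, isolating the pleiotropy-induced bias the
    Egger intercept should recover.
    ``outlier``: theta = 0.5 with 10 instruments, one of which carries a
    10-SE outcome offset; small set so the outlier visibly distorts IVW.
    ``reverse``: causation runs outcome -> exposure (direction testing).
    """
    presets = {
        "null": dict(theta=0.0, n_snp=80),
        "causal": dict(theta=0.5, n_snp=80),
        "directional_pleiotropy": dict(
            theta=0.0,
            n_snp=80,
            pleiotropy="directional",
            pleiotropy_mean=0.01,
            pleiotropy_sd=0.005,
        ),
        "outlier": dict(theta=0.5, n_snp=10, outlier_count=1, outlier_offset=10.0),
        "reverse": dict(theta=0.5, n_snp=80, reverse=True),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    return SimulationConfig(seed=seed, **presets[name])


def _se_gwas(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _exact_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def simulate_study(config: SimulationConfig) -> tuple[SummaryDataset, SummaryDataset, SimulationTruth]:
    """Generate exposure and outcome summary datasets plus their truth.

    Allele swaps, strand flips and duplicate rows perturb only the
    outcome file (instrument selection on the exposure side stays clean);
    palindromic planting changes the variant's allele pair in both files,
    since a variant's alleles are a property of the variant itself.
    """
    master = np.random.SeedSequence(config.seed)
    rng_effects, rng_noise, rng_alleles = (np.random.default_rng(s) for s in master.spawn(3))
    k = config.n_snp

    snp_ids = [f"rs{j + 1:06d}" for j in range(k)]
    chroms = [str(j % 22 + 1) for j in range(k)]
    positions = [1_000_000 + 20_000_000 * (j // 22) for j in range(k)]  # far apart within chrom

    maf = rng_effects.uniform(*config.maf_range, size=k)
    if config.gamma_fixed is not None:
        gamma = np.asarray(config.gamma_fixed, dtype=float)
        if gamma.shape != (k,):
            raise ValueError("gamma_fixed length must equal n_snp")
    else:
        gamma = rng_effects.normal(config.gamma_mean, config.gamma_sd, size=k)

    if config.pleiotropy == "none":
        alpha = np.zeros(k)
    elif config.pleiotropy == "balanced":
        alpha = rng_effects.normal(0.0, config.pleiotropy_sd, size=k)
    else:
        alpha = rng_effects.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)

    se_exp = _se_gwas(maf, config.n_exp)
    se_out = _se_gwas(maf, config.n_out)

    mu_exp = gamma
    mu_out = config.theta * gamma + alpha
    if config.reverse:
        # true causation runs outcome trait -> exposure trait
        mu_exp, mu_out = config.theta * gamma + alpha, gamma

    outlier_idx = (
        rng_effects.choice(k, size=config.outlier_count, replace=False)
        if config.outlier_count
        else np.array([], dtype=int)
    )
    mu_out = mu_out.copy()
    mu_out[outlier_idx] += config.outlier_offset * se_out[outlier_idx]

    # allele assignment, with palindromic planting shared by both files
    n_pal = _exact_count(config.palindromic_fraction, k)
    pal_idx = set(rng_alleles.choice(k, size=n_pal, replace=False).tolist()) if n_pal else set()
    alleles: list[tuple[str, str]] = []
    for j in range(k):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng_alleles.integers(len(pool))])

    beta_exp = mu_exp + rng_noise.normal(0.0, se_exp)
    beta_out = mu_out + rng_noise.normal(0.0, se_out)

    def record(j, beta, se, n):
        return SummaryStatRecord(
            snp_id=snp_ids[j],
            chrom=chroms[j],
            pos=positions[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(maf[j]),
            beta=float(beta),
            se=float(se),
            pval=float(max(np.finfo(float).tiny, 2.0 * stats.norm.sf(abs(beta / se)))),
            n=float(n),
        )

    exp_records = [record(j, beta_exp[j], se_exp[j], config.n_exp) for j in range(k)]
    out_records = [record(j, beta_out[j], se_out[j], config.n_out) for j in range(k)]

    # outcome-side harmonization noise; palindromic SNPs excluded because
    # their swap/flip representations are indistinguishable
    editable = [j for j in range(k) if j not in pal_idx]
    rng_alleles.shuffle(editable)
    n_swap = min(_exact_count(config.swap_fraction, k), len(editable))
    swap_idx, editable = editable[:n_swap], editable[n_swap:]
    n_flip = min(_exact_count(config.flip_fraction, k), len(editable))
    flip_idx = editable[:n_flip]

    for j in swap_idx:
        r = out_records[j]
        r.effect_allele, r.other_allele = r.other_allele, r.effect_allele
        r.beta = -r.beta
        r.eaf = 1.0 - r.eaf
    for j in flip_idx:
        r = out_records[j]
        r.effect_allele = COMPLEMENT[r.effect_allele]
        r.other_allele = COMPLEMENT[r.other_allele]

    n_dup = _exact_count(config.duplicate_fraction, k)
    if n_dup:
        dup_idx = rng_alleles.choice(k, size=n_dup, replace=False)
        for j in sorted(dup_idx.tolist()):
            src = out_records[j]
            dup = replace(src, se=src.se * 2.0)
            dup.pval = float(max(np.finfo(float).tiny, 2.0 * stats.norm.sf(abs(dup.beta / dup.se))))
            out_records.append(dup)

    truth = SimulationTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        outlier_ids=[snp_ids[j] for j in sorted(outlier_idx.tolist())],
        palindromic_ids=[snp_ids[j] for j in sorted(pal_idx)],
        seed=config.seed,
    )
    exposure = SummaryDataset("simulated_exposure", "binary", exp_records, n_default=config.n_exp)
    outcome = SummaryDataset("simulated_outcome", "binary", out_records, n_default=config.n_out)
    return exposure, outcome, truth


def simulate_harmonized(
    config: SimulationConfig,
    policy: str = "remove",
) -> tuple[list[HarmonizedInstrument], SimulationTruth]:
    """Convenience path for replicate studies: simulate, dedup, harmonize."""
    exposure, outcome, truth = simulate_study(config)
    insts, _ = harmonize_datasets(exposure, dedup_records(outcome), policy=policy)
    return insts, truth
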