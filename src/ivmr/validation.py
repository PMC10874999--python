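"""Replicate validation studies over the synthetic-data scenarios.

Each study runs the full simulate -> harmonize -> estimate path many
times under a named scenario and summarises an operating characteristic:
type-I error of the random-effects IVW test, uniformity of Cochran's Q
p-values under the null, recovery and confidence-interval coverage of a
true causal effect, Egger-intercept recovery of directional pleiotropy,
outlier detection and correction by the residual-sum test, and direction
recovery by the Steiger test.  These are the checks a practitioner would
want before trusting the estimators on real summary statistics; they are
shared by the test suite and the results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import ivw
from .harmonize import harmonize_datasets
from .sensitivity import cochran_q, mr_presso
from .simulate import SimulationConfig, scenario, simulate_harmonized, simulate_study
from .steiger import steiger_test
from .sumstats import dedup_records


def _replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)


def ivw_null_rejection_rate(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of null-scenario replicates where random-effects IVW rejects."""
    rejections = 0
    for rep_seed in _replicate_seeds(seed, n_reps):
        insts, _ = simulate_harmonized(scenario("null", int(rep_seed)))
        rejections += ivw(insts, model="random").pval < alpha
    return rejections / n_reps


def q_pvalue_ks_distance(n_reps: int = 500, seed: int = 0) -> float:
    """KS distance of null-scenario Cochran's Q p-values from uniform."""
    pvals = np.empty(n_reps)
    for i, rep_seed in enumerate(_replicate_seeds(seed, n_reps)):
        insts, _ = simulate_harmonized(scenario("null", int(rep_seed)))
        pvals[i] = cochran_q(insts)[2]
    return float(stats.kstest(pvals, "uniform").statistic)


@dataclass
class RecoveryStudy:
    theta: float
    estimates: np.ndarray
    covered: np.ndarray  # True when the 95% CI contains theta

    @property
    def median_estimate(self) -> float:
        return float(np.median(self.estimates))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.covered))


def causal_recovery_study(n_reps: int = 200, seed: int = 0) -> RecoveryStudy:
    """Random-effects IVW estimates and CI coverage under the causal scenario."""
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    theta = scenario("causal", 0).theta
    for i, rep_seed in enumerate(_replicate_seeds(seed, n_reps)):
        insts, truth = simulate_harmonized(scenario("causal", int(rep_seed)))
        res = ivw(insts, model="random")
        estimates[i] = res.beta
        lo, hi = res.beta - 1.959964 * res.se, res.beta + 1.959964 * res.se
        covered[i] = lo <= truth.theta <= hi
    return RecoveryStudy(theta=theta, estimates=estimates, covered=covered)


def egger_intercept_study(n_reps: int = 200, seed: int = 0) -> tuple[np.ndarray, float]:
    """Egger intercepts under directional pleiotropy; returns (intercepts, true mean alpha)."""
    from .estimators import egger

    config = scenario("directional_pleiotropy", 0)
    intercepts = np.empty(n_reps)
    for i, rep_seed in enumerate(_replicate_seeds(seed, n_reps)):
        insts, _ = simulate_harmonized(scenario("directional_pleiotropy", int(rep_seed)))
        intercepts[i] = egger(insts).extra["egger_intercept"]
    return intercepts, config.pleiotropy_mean


@dataclass
class OutlierStudy:
    detection_rate: float  # planted SNP flagged and global p significant
    improvement_rate: float  # corrected estimate strictly closer to theta


def presso_outlier_study(n_reps: int = 200, seed: int = 0, n_sim: int = 200) -> OutlierStudy:
    """Detection and correction of the planted outlier across replicates."""
    detected = np.zeros(n_reps, dtype=bool)
    improved = np.zeros(n_reps, dtype=bool)
    for i, rep_seed in enumerate(_replicate_seeds(seed, n_reps)):
        insts, truth = simulate_harmonized(scenario("outlier", int(rep_seed)))
        res = mr_presso(insts, n_sim=n_sim, seed=int(rep_seed))
        planted = truth.outlier_ids[0]
        detected[i] = planted in res.outlier_ids and res.global_p <= 0.05
        if res.corrected is not None:
            full = ivw(insts, model="random")
            improved[i] = abs(res.corrected.beta - truth.theta) < abs(full.beta - truth.theta)
    return OutlierStudy(
        detection_rate=float(detected.mean()),
        improvement_rate=float(improved.mean()),
    )


def steiger_direction_rate(scenario_name: str, n_reps: int = 200, seed: int = 0) -> float:
    """Fraction of replicates where the Steiger flag says exposure -> outcome."""
    correct = 0
    for rep_seed in _replicate_seeds(seed, n_reps):
        config = scenario(scenario_name, int(rep_seed))
        insts, _ = simulate_harmonized(config)
        res = steiger_test(insts, config.n_exp, config.n_out)
        correct += res.correct_direction
    return correct / n_reps


@dataclass
class HarmonizationAudit:
    n_snp: int
    n_swapped: int
    n_swaps_recovered: int
    n_palindromic: int
    n_palindromic_removed: int
    n_retained: int

    @property
    def counts_conserved(self) -> bool:
        return self.n_retained == self.n_snp - self.n_palindromic_removed

    @property
    def swap_recovery_rate(self) -> float:
        return self.n_swaps_recovered / self.n_swapped if self.n_swapped else 1.0


def harmonization_audit(
    seed: int = 0,
    n_snp: int = 50,
    swap_fraction: float = 0.2,
    palindromic_fraction: float = 0.1,
) -> HarmonizationAudit:
    """Plant allele swaps and palindromes, then audit the cleaning stages."""
    config = SimulationConfig(
        n_snp=n_snp,
        theta=0.5,
        swap_fraction=swap_fraction,
        palindromic_fraction=palindromic_fraction,
        seed=seed,
    )
    exposure, outcome, truth = simulate_study(config)
    insts, log = harmonize_datasets(exposure, dedup_records(outcome))

    exp_by_id = {r.snp_id: r for r in exposure.records}
    out_by_id = {r.snp_id: r for r in outcome.records}
    swapped_ids = [
        r.snp_id
        for r in outcome.records
        if (r.effect_allele, r.other_allele)
        == (exp_by_id[r.snp_id].other_allele, exp_by_id[r.snp_id].effect_allele)
        and not {r.effect_allele, r.other_allele} in ({"A", "T"}, {"C", "G"})
    ]
    by_id = {i.snp_id: i for i in insts}
    recovered = sum(
        1
        for s in swapped_ids
        if s in by_id and by_id[s].beta_out == -out_by_id[s].beta
    )
    return HarmonizationAudit(
        n_snp=n_snp,
        n_swapped=len(swapped_ids),
        n_swaps_recovered=recovered,
        n_palindromic=len(truth.palindromic_ids),
        n_palindromic_removed=len(log.removed_palindromic),
        n_retained=len(insts),
    )
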