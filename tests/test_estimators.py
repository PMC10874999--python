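import numpy as np
import pytest
from scipy import stats

from ivmr.estimators import (
    Z95,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from ivmr.harmonize import HarmonizedInstrument


def inst(snp_id, bx, by, sy, sx=0.01):
    return HarmonizedInstrument(snp_id, bx, sx, by, sy)


def random_instruments(rng, k):
    bx = rng.uniform(0.05, 0.6, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.01, 0.2, k)
    by = rng.normal(0.3 * bx, sy)
    return [inst(f"rs{j}", bx[j], by[j], sy[j]) for j in range(k)]


def wls_origin_oracle(insts):
    """Weighted regression through the origin of beta_out on beta_exp."""
    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    w = 1.0 / np.array([i.se_out for i in insts]) ** 2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return beta, se


def wls_with_intercept_oracle(insts):
    """Closed-form weighted least squares of beta_out on beta_exp."""
    x = np.abs([i.beta_exp for i in insts])
    y = np.array([i.beta_out * np.sign(i.beta_exp) for i in insts])
    w = 1.0 / np.array([i.se_out for i in insts]) ** 2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    return slope, intercept


class TestWaldRatio:
    def test_direct_formula(self):
        res = wald_ratio(inst("rs1", 0.5, 0.25, 0.05))
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        res = wald_ratio(inst("rs1", 0.5, 0.0, 0.05))
        assert res.beta == 0.0
        assert res.pval == 1.0

    def test_negative_exposure_effect_keeps_se_positive(self):
        res = wald_ratio(inst("rs1", -0.5, 0.25, 0.05))
        assert res.beta == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="beta_exp"):
            wald_ratio(inst("rs1", 0.0, 0.25, 0.05))


class TestIVW:
    def test_hand_fixture(self, three_instruments):
        res = ivw(three_instruments, model="fixed")
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(1 / 150), abs=1e-12)
        assert res.n_snp == 3

    def test_matches_weighted_regression_through_origin(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            insts = random_instruments(rng, int(rng.integers(2, 15)))
            res = ivw(insts, model="fixed")
            beta, se = wls_origin_oracle(insts)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_single_instrument_reduces_to_wald(self):
        one = inst("rs1", 0.5, 0.25, 0.05)
        res = ivw([one], model="fixed")
        wald = wald_ratio(one)
        assert res.beta == pytest.approx(wald.beta)
        assert res.se == pytest.approx(wald.se)

    def test_identical_instruments_have_zero_q_and_equal_models(self):
        insts = [inst(f"rs{j}", 0.5, 0.25, 0.05) for j in range(4)]
        fe, re = ivw(insts, model="fixed"), ivw(insts, model="random")
        assert fe.beta == re.beta == pytest.approx(0.5)
        assert re.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert fe.se == re.se

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            insts = random_instruments(rng, int(rng.integers(2, 12)))
            assert ivw(insts, model="random").se >= ivw(insts, model="fixed").se - 1e-15

    def test_single_instrument_random_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            res = ivw([inst("rs1", 0.5, 0.25, 0.05)], model="random")
        assert res.method == "ivw_fe"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ivw([], model="fixed")

    def test_invariant_under_allele_recoding(self, three_instruments):
        recoded = list(three_instruments)
        i = recoded[1]
        recoded[1] = HarmonizedInstrument(i.snp_id, -i.beta_exp, i.se_exp, -i.beta_out, i.se_out)
        assert ivw(recoded).beta == pytest.approx(ivw(three_instruments).beta, abs=1e-14)


class TestEgger:
    def test_hand_fixture_matches_weighted_ls_oracle(self, three_instruments):
        res = egger(three_instruments)
        slope, intercept = wls_with_intercept_oracle(three_instruments)
        assert slope == pytest.approx(0.613, abs=5e-4)
        assert intercept == pytest.approx(-0.047, abs=5e-4)
        assert res.beta == pytest.approx(slope, abs=1e-10)
        assert res.extra["egger_intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            insts = random_instruments(rng, int(rng.integers(3, 15)))
            res = egger(insts)
            slope, intercept = wls_with_intercept_oracle(insts)
            assert res.beta == pytest.approx(slope, abs=1e-10)
            assert res.extra["egger_intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_exact_proportionality_recovers_theta_with_zero_intercept(self):
        theta = 0.7
        gammas = [0.1, 0.2, 0.3, 0.45]
        insts = [inst(f"rs{j}", g, theta * g, 0.05) for j, g in enumerate(gammas)]
        res = egger(insts)
        assert res.beta == pytest.approx(theta, abs=1e-12)
        assert res.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_outcome_shift_moves_intercept_only(self):
        gammas = [0.1, 0.2, 0.3, 0.45]
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.02, len(gammas))
        base = [inst(f"rs{j}", g, 0.5 * g + noise[j], 0.05) for j, g in enumerate(gammas)]
        shifted = [inst(i.snp_id, i.beta_exp, i.beta_out + 0.04, i.se_out) for i in base]
        r0, r1 = egger(base), egger(shifted)
        assert r1.beta == pytest.approx(r0.beta, abs=1e-10)
        assert r1.extra["egger_intercept"] - r0.extra["egger_intercept"] == pytest.approx(0.04, abs=1e-10)

    def test_internal_orientation_makes_recoding_invariant(self):
        rng = np.random.default_rng(9)
        insts = random_instruments(rng, 8)
        recoded = [
            HarmonizedInstrument(i.snp_id, -i.beta_exp, i.se_exp, -i.beta_out, i.se_out)
            if j % 2
            else i
            for j, i in enumerate(insts)
        ]
        a, b = egger(insts), egger(recoded)
        assert b.beta == pytest.approx(a.beta, abs=1e-12)
        assert b.extra["egger_intercept"] == pytest.approx(a.extra["egger_intercept"], abs=1e-12)

    def test_fewer_than_three_instruments_rejected(self):
        with pytest.raises(ValueError, match="3"):
            egger([inst("rs1", 0.5, 0.25, 0.05), inst("rs2", 0.4, 0.2, 0.05)])


class TestWeightedMedian:
    def test_hand_fixture_hits_middle_ratio(self, three_instruments):
        res = weighted_median(three_instruments, n_boot=200, seed=42)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.extra["n_boot"] == 200

    def test_equal_weight_interpolation(self):
        # equal weights, ratios {0.1, 0.2, 0.8, 0.9}: interpolate to 0.5
        point = weighted_median_point(np.array([0.1, 0.2, 0.8, 0.9]), np.ones(4))
        assert point == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_cumulative_weight_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            k = int(rng.integers(3, 12))
            ratios, weights = rng.normal(0.5, 0.3, k), rng.uniform(0.1, 5, k)
            # oracle: explicit cumulative-midpoint interpolation
            order = np.argsort(ratios)
            t, w = ratios[order], weights[order] / weights.sum()
            s = np.cumsum(w) - w / 2
            expected = float(np.interp(0.5, s, t))
            assert weighted_median_point(ratios, weights) == pytest.approx(expected, abs=1e-12)
            assert min(ratios) - 1e-12 <= expected <= max(ratios) + 1e-12

    def test_degenerate_common_ratio(self):
        insts = [inst(f"rs{j}", 0.2 + 0.1 * j, 0.3 * (0.2 + 0.1 * j), 0.001, sx=0.0001) for j in range(4)]
        res = weighted_median(insts, n_boot=300, seed=7)
        assert res.beta == pytest.approx(0.3, abs=1e-12)
        assert res.se < 0.05

    def test_breakdown_resistance_to_minority_outliers(self):
        # >50% of weight shares theta = 0.5; two gross outliers elsewhere
        rng = np.random.default_rng(15)
        good = [inst(f"g{j}", 0.3, 0.15 + rng.normal(0, 0.002), 0.01) for j in range(6)]
        bad = [inst(f"b{j}", 0.3, 0.9, 0.01) for j in range(2)]
        res = weighted_median(good + bad, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.5, abs=0.05)

    def test_seed_reproducibility(self, three_instruments):
        a = weighted_median(three_instruments, n_boot=100, seed=3)
        b = weighted_median(three_instruments, n_boot=100, seed=3)
        c = weighted_median(three_instruments, n_boot=100, seed=4)
        assert a.se == b.se
        assert a.se != c.se


class TestOddsRatioScale:
    def test_closed_form_ci(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-Z95 * 0.1), abs=1e-9)
        assert hi == pytest.approx(np.exp(Z95 * 0.1), abs=1e-9)
        assert (round(lo, 3), round(hi, 3)) == (0.822, 1.217)

    def test_zero_se_collapses_interval(self):
        or_, lo, hi = to_odds_ratio(np.log(2), 0.0)
        assert or_ == lo == hi == pytest.approx(2.0)

    def test_published_scale_consistency(self):
        # a log-odds of 0.916 corresponds to an OR of ~2.50
        assert np.exp(0.916) == pytest.approx(2.499, abs=5e-3)


def test_pvalues_well_formed(three_instruments):
    for res in (
        ivw(three_instruments, model="fixed"),
        ivw(three_instruments, model="random"),
        egger(three_instruments),
        weighted_median(three_instruments, n_boot=100, seed=0),
    ):
        assert 0 < res.pval <= 1
        assert res.ci_low < res.or_ < res.ci_high
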