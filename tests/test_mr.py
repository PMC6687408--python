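import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dtmr
from dtmr import (
    RCT_REDUCTIONS,
    InstrumentSet,
    LdMatrix,
    egger_regression,
    ivw_correlated,
    or_to_rr,
    scale_to_rct,
    wald_ratio,
    weighted_median,
)


def make_instruments(x, sx, ld=None):
    n = len(x)
    ids = [f"rs{i}" for i in range(n)]
    records = pd.DataFrame(
        {
            "SNP": ids,
            "EA": "A",
            "OA": "G",
            "EAF": 0.3,
            "BETA": x,
            "SE": sx,
            "P": 1e-9,
            "N": 100_000,
        }
    )
    ld = ld if ld is not None else LdMatrix(ids, np.eye(n))
    return InstrumentSet("CCB", records, ld)


def make_outcome(y, sy, n):
    return pd.DataFrame({"SNP": [f"rs{i}" for i in range(n)], "BETA": y, "SE": sy})


class TestWaldRatio:
    def test_unit_exposure(self):
        res = wald_ratio(1.0, 0.1, 0.5, 0.1)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_null_outcome(self):
        res = wald_ratio(1.0, 0.1, 0.0, 0.1)
        assert res.beta == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.2, 0.05)

    def test_delta_method_se_matches_parametric_bootstrap(self):
        res = wald_ratio(-0.4, 0.0, 0.2, 0.05)
        assert res.beta == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.125)
        rng = np.random.default_rng(0)
        draws = rng.normal(0.2, 0.05, 200_000) / -0.4
        assert res.se == pytest.approx(draws.std(ddof=1), rel=0.05)


class TestIvwCorrelated:
    def test_identity_ld_equals_closed_form_ivw(self):
        rng = np.random.default_rng(1)
        n = 6
        x, sx = rng.uniform(0.5, 1.5, n), rng.uniform(0.02, 0.1, n)
        y, sy = rng.normal(0.3, 0.1, n), rng.uniform(0.02, 0.1, n)
        res = ivw_correlated(make_instruments(x, sx), make_outcome(y, sy, n))
        # textbook fixed-effect IVW of per-variant Wald ratios
        ratios = y / x
        w = x**2 / sy**2  # inverse variance of each ratio
        expected = (w * ratios).sum() / w.sum()
        assert res.beta == pytest.approx(expected, rel=1e-10)
        assert res.se == pytest.approx(math.sqrt(1 / w.sum()), rel=1e-10)

    def test_single_instrument_degenerates_to_wald(self):
        res = ivw_correlated(make_instruments([0.8], [0.05]), make_outcome([0.2], [0.04], 1))
        wald = wald_ratio(0.8, 0.05, 0.2, 0.04)
        assert res.beta == pytest.approx(wald.beta)
        assert res.se == pytest.approx(wald.se)

    def test_matches_explicit_gls_inversion(self):
        x = np.array([1.0, 0.8, 1.2])
        y = np.array([0.5, 0.45, 0.6])
        sy = np.array([0.05, 0.06, 0.04])
        r = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        ld = LdMatrix(["rs0", "rs1", "rs2"], r)
        res = ivw_correlated(make_instruments(x, [0.01] * 3, ld), make_outcome(y, sy, 3))
        sigma = r * np.outer(sy, sy)
        sigma_inv = np.linalg.inv(sigma)
        beta = (x @ sigma_inv @ y) / (x @ sigma_inv @ x)
        assert res.beta == pytest.approx(beta, rel=1e-10)
        assert res.se == pytest.approx(math.sqrt(1 / (x @ sigma_inv @ x)), rel=1e-10)

    def test_cochran_q_follows_chi2_under_homogeneity(self):
        rng = np.random.default_rng(2)
        n, reps = 8, 400
        x = rng.uniform(0.5, 1.5, n)
        sy = np.full(n, 0.05)
        qs = []
        for _ in range(reps):
            y = 0.4 * x + rng.normal(0, sy)
            qs.append(
                ivw_correlated(make_instruments(x, [0.01] * n), make_outcome(y, sy, n)).heterogeneity_q
            )
        # mean of chi2(n-1) is n-1
        assert np.mean(qs) == pytest.approx(n - 1, rel=0.1)


class TestEgger:
    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            egger_regression(make_instruments([1.0, 1.1], [0.01] * 2), make_outcome([0.5, 0.55], [0.05] * 2, 2))

    def test_no_pleiotropy_recovers_common_ratio(self):
        x = np.array([0.6, 1.0, 1.4, 0.8])
        y = 0.5 * x
        res = egger_regression(make_instruments(x, [0.01] * 4), make_outcome(y, [0.05] * 4, 4))
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_recovers_planted_intercept(self):
        x = np.array([0.6, 1.0, 1.4, 0.8, 1.2])
        y = 0.02 + 0.5 * x
        res = egger_regression(make_instruments(x, [0.001] * 5), make_outcome(y, [0.001] * 5, 5))
        assert res.egger_intercept == pytest.approx(0.02, abs=1e-6)
        assert res.beta == pytest.approx(0.5, abs=1e-6)

    def test_matches_two_parameter_gls_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 1.5, 4)
        y = rng.normal(0.3, 0.2, 4)
        sy = rng.uniform(0.03, 0.08, 4)
        ld = LdMatrix(
            [f"rs{i}" for i in range(4)],
            np.array(
                [
                    [1.0, 0.4, 0.0, 0.0],
                    [0.4, 1.0, 0.0, 0.0],
                    [0.0, 0.0, 1.0, -0.3],
                    [0.0, 0.0, -0.3, 1.0],
                ]
            ),
        )
        res = egger_regression(make_instruments(x, [0.01] * 4, ld), make_outcome(y, sy, 4))
        sigma = ld.r * np.outer(sy, sy)
        design = np.column_stack([np.ones(4), x])
        cov = np.linalg.inv(design.T @ np.linalg.inv(sigma) @ design)
        coef = cov @ design.T @ np.linalg.inv(sigma) @ y
        assert res.egger_intercept == pytest.approx(coef[0], rel=1e-9)
        assert res.beta == pytest.approx(coef[1], rel=1e-9)
        assert res.se == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-9)


def exhaustive_weighted_median(ratios, weights):
    """Scan of the weighted-quantile definition: the smallest ratio whose
    cumulative normalized weight reaches one half."""
    order = np.argsort(ratios)
    total = 0.0
    for i in order:
        total += weights[i] / weights.sum()
        if total >= 0.5 - 1e-12:
            return ratios[i]
    raise AssertionError


class TestWeightedMedian:
    def test_equal_weights_gives_plain_median(self):
        x = np.ones(5)
        y = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = weighted_median(make_instruments(x, [0.01] * 5), make_outcome(y, [0.05] * 5, 5), n_boot=50)
        assert res.beta == pytest.approx(0.3)

    def test_dominant_weight_returns_that_ratio(self):
        x = np.ones(3)
        y = np.array([0.1, 0.9, 0.5])
        sy = np.array([0.01, 1.0, 1.0])  # first variant carries >50% weight
        res = weighted_median(make_instruments(x, [0.01] * 3), make_outcome(y, sy, 3), n_boot=50)
        assert res.beta == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.uniform(0.5, 1.5, n)
        y = rng.normal(0.2, 0.3, n)
        sy = rng.uniform(0.02, 0.3, n)
        res = weighted_median(make_instruments(x, [0.01] * n), make_outcome(y, sy, n), n_boot=10)
        ratios = y / x
        weights = (x / sy) ** 2
        assert res.beta == pytest.approx(exhaustive_weighted_median(ratios, weights))

    def test_bootstrap_is_seeded(self):
        x = np.array([1.0, 0.9, 1.1, 1.2])
        y = np.array([0.5, 0.4, 0.6, 0.5])
        a = weighted_median(make_instruments(x, [0.05] * 4), make_outcome(y, [0.05] * 4, 4), seed=5)
        b = weighted_median(make_instruments(x, [0.05] * 4), make_outcome(y, [0.05] * 4, 4), seed=5)
        assert a.se == b.se


class TestScaleToRct:
    def test_acei_scaling_constant(self):
        res = dtmr.MRResult("ivw_correlated", -0.01, 0.002, 10)
        scaled = scale_to_rct(res, RCT_REDUCTIONS["ACEI"])
        assert scaled.beta == pytest.approx(-0.2114)

    def test_unit_reduction_is_identity(self):
        res = dtmr.MRResult("wald", -0.03, 0.01, 1)
        scaled = scale_to_rct(res, dtmr.DrugClassDefinition("X", 1.0))
        assert scaled.beta == res.beta and scaled.se == res.se

    def test_z_statistic_and_p_invariant(self):
        res = dtmr.MRResult("ivw_correlated", -0.05, 0.02, 6)
        scaled = scale_to_rct(res, RCT_REDUCTIONS["BB"])
        assert scaled.beta == pytest.approx(-0.4755)
        assert scaled.se == pytest.approx(0.1902)
        assert scaled.beta / scaled.se == pytest.approx(res.beta / res.se)
        assert scaled.pvalue == pytest.approx(res.pvalue)
        # CI recomputed on the scaled estimate
        assert scaled.ci_low == pytest.approx(scaled.beta - 1.959964 * scaled.se)


def rr_from_2x2(odds_ratio, p0):
    """Contingency-table oracle: exposed risk from baseline odds times OR."""
    odds0 = p0 / (1 - p0)
    odds1 = odds_ratio * odds0
    p1 = odds1 / (1 + odds1)
    return p1 / p0


class TestOrToRr:
    def test_null_or(self):
        for p0 in (0.01, 0.05, 0.5):
            assert or_to_rr(1.0, p0) == pytest.approx(1.0)

    def test_rare_disease_limit(self):
        assert or_to_rr(2.0, 1e-8) == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("odds_ratio", [0.21, 0.67, 0.75, 1.02, 2.0, 5.0])
    @pytest.mark.parametrize("p0", [0.01, 0.05, 0.10])
    def test_matches_contingency_oracle(self, odds_ratio, p0):
        assert or_to_rr(odds_ratio, p0) == pytest.approx(rr_from_2x2(odds_ratio, p0), rel=1e-12)

    def test_example_value(self):
        assert or_to_rr(2.0, 0.1) == pytest.approx(2.0 / 1.1)

    def test_monotone_in_or_and_shrinks_with_incidence(self):
        ors = np.linspace(0.2, 3.0, 20)
        rrs = [or_to_rr(o, 0.05) for o in ors]
        assert all(a < b for a, b in zip(rrs, rrs[1:]))
        # larger baseline incidence pulls the log effect toward 0
        for o in (0.5, 2.0):
            lo = abs(math.log(or_to_rr(o, 0.01)))
            hi = abs(math.log(or_to_rr(o, 0.30)))
            assert hi < lo


class TestOrientation:
    def test_protective_effect_reads_as_rr_below_one(self, demo_bundle):
        b = demo_bundle
        sel = dtmr.select_instruments(b.sumstats_sbp, b.regions, b.true_ld, drug_class="CCB")
        out, _ = dtmr.harmonize_sumstats(sel.records, b.sumstats_outcomes["CHD"])
        oriented, out_oriented = dtmr.orient_to_sbp_lowering(sel, out)
        assert (oriented.records["BETA"] > 0).all()
        res = scale_to_rct(ivw_correlated(oriented, out_oriented), RCT_REDUCTIONS["CCB"])
        # a positive mmHg->outcome log-OR was planted, so lowering protects
        assert res.odds_ratio < 1.0
        truth = math.exp(-b.truth.outcome_log_or_per_mmhg["CHD"] * 8.90)
        assert res.ci_low < math.log(truth) < res.ci_high

    def test_orientation_leaves_ratio_invariant(self):
        x = np.array([0.5, -0.7, 0.9])
        y = np.array([0.1, 0.2, -0.3])
        inst = make_instruments(x, [0.05] * 3)
        out = make_outcome(y, [0.05] * 3, 3)
        oriented, out_o = dtmr.orient_to_sbp_lowering(inst, out)
        # per-variant ratios on the mmHg-lower scale equal -y/x
        np.testing.assert_allclose(
            out_o["BETA"].to_numpy() / oriented.records["BETA"].to_numpy(), -y / x
        )
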