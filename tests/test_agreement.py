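"""Interrater agreement statistics: ICC(2,1), Bland-Altman, Dice, logit t-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pftquant.agreement import (
    RatingMatrix,
    bland_altman,
    build_report,
    dice,
    icc_2_1,
    logit,
    paired_t_logit_dsc,
)
from pftquant.errors import PFTQuantError
from pftquant.synthetic import simulate_rating_table


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        r = icc_2_1(RatingMatrix(np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])))
        assert r.estimate == pytest.approx(1.0)
        assert r.label == "excellent"

    def test_hand_computed_anova_oracle(self):
        # [[1,2],[3,4],[5,6]]: MSR=8, MSC=1.5, MSE=0 -> ICC = 8/9.
        r = icc_2_1(RatingMatrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])))
        assert r.estimate == pytest.approx(8 / 9, abs=1e-12)
        assert r.ci95[0] <= r.estimate <= r.ci95[1]

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        vals = simulate_rating_table(50, 9, 3, 50, seed=42)
        mine = icc_2_1(RatingMatrix(vals))
        df = pd.DataFrame({
            "exam": np.repeat(np.arange(50), 2),
            "rater": list(range(2)) * 50,
            "y": vals.ravel(),
        })
        table = pg.intraclass_corr(df, "exam", "rater", "y")
        ref = table[table["Type"] == "ICC(A,1)"].iloc[0]
        assert mine.estimate == pytest.approx(ref["ICC"], abs=1e-9)
        assert mine.ci95 == pytest.approx(tuple(ref["CI95"]), abs=0.006)

    def test_consistency_identity_with_pearson(self, rng):
        # With k=2 and columns sharing mean and variance, the consistency
        # coefficient (MSR-MSE)/(MSR+MSE) equals Pearson r exactly; the
        # absolute-agreement ICC(2,1) differs only by an O(1/n) term.
        from scipy import stats

        x = rng.normal(10, 4, 60)
        y = np.roll(x, 11)
        r = stats.pearsonr(x, y).statistic
        res = icc_2_1(RatingMatrix(np.column_stack([x, y])))
        consistency = (res.ms_rows - res.ms_error) / (res.ms_rows + res.ms_error)
        assert consistency == pytest.approx(r, abs=1e-9)
        assert res.estimate == pytest.approx(r, abs=0.02)

    def test_constant_matrix_has_no_variance(self):
        with pytest.raises(PFTQuantError, match="no variance"):
            icc_2_1(RatingMatrix(np.full((4, 2), 3.0)))

    def test_too_few_exams_rejected(self):
        with pytest.raises(PFTQuantError, match="n >= 3"):
            RatingMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))

    @pytest.mark.parametrize("pop_icc,sb,sr", [(0.9, 9.0, 3.0), (0.7, np.sqrt(7), np.sqrt(3)), (0.5, 3.0, 3.0)])
    def test_estimator_recovers_population_icc(self, pop_icc, sb, sr):
        ests = [
            icc_2_1(RatingMatrix(simulate_rating_table(200, sb, sr, 40, seed=7000 + i))).estimate
            for i in range(100)
        ]
        assert abs(np.mean(ests) - pop_icc) <= 0.02

    def test_estimate_never_exceeds_one(self, rng):
        for i in range(20):
            v = rng.normal(0, 5, size=(10, 3))
            assert icc_2_1(RatingMatrix(v)).estimate <= 1.0


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert r.mean_diff == 0.0 and r.loa == (0.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30), st.integers(0, 2**31 - 1))
    def test_loa_midpoint_identity(self, xs, seed):
        x = np.asarray(xs)
        y = x + np.random.default_rng(seed).normal(0, 5, x.size)
        r = bland_altman(x, y)
        assert (r.loa[0] + r.loa[1]) / 2 == pytest.approx(r.mean_diff, abs=1e-9)
        assert r.loa[0] <= r.mean_diff <= r.loa[1]

    def test_normal_differences_match_population_limits(self):
        # d ~ N(-4.5, 17.8^2): population limits are -4.5 +/- 1.96*17.8.
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 100_000)
        x = y + rng.normal(-4.5, 17.8, 100_000)
        r = bland_altman(x, y)
        assert r.loa[0] == pytest.approx(-39.4, abs=0.5)
        assert r.loa[1] == pytest.approx(30.4, abs=0.5)

    def test_single_pair_rejected(self):
        with pytest.raises(PFTQuantError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestDice:
    def test_formula_and_symmetry(self, rng):
        shape = (4, 16, 16)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a.ravel()[:4] = True
        b.ravel()[1:7] = True  # |a|=4, |b|=6, overlap 3
        assert dice(a, b) == pytest.approx(0.6)
        assert dice(a, b) == dice(b, a)
        assert dice(a, a) == 1.0

    def test_disjoint_and_empty(self):
        a = np.zeros((2, 16, 16), bool)
        b = np.zeros((2, 16, 16), bool)
        a[0, 0, 0] = True
        b[1, 5, 5] = True
        assert dice(a, b) == 0.0
        assert dice(np.zeros((2, 16, 16), bool), np.zeros((2, 16, 16), bool)) == 1.0

    def test_geometry_mismatch(self):
        with pytest.raises(PFTQuantError, match="mismatch"):
            dice(np.zeros((2, 16, 16), bool), np.zeros((3, 16, 16), bool))


class TestLogit:
    def test_symmetry_point_and_value(self):
        assert logit(0.5) == 0.0
        assert logit(0.88) == pytest.approx(np.log(22 / 3), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.001, 0.999))
    def test_antisymmetry(self, v):
        assert logit(v) + logit(1 - v) == pytest.approx(0.0, abs=1e-9)

    def test_boundary_requires_explicit_clamp(self):
        with pytest.raises(PFTQuantError, match="clamp"):
            logit(1.0)
        assert logit(1.0, clamp_eps=1e-6) == pytest.approx(np.log((1 - 1e-6) / 1e-6))


class TestPairedLogitT:
    def test_constant_logit_shift_is_degenerate(self):
        d1 = np.array([0.80, 0.85, 0.90, 0.75])
        shift = 0.3
        d2 = 1 / (1 + np.exp(-(np.log(d1 / (1 - d1)) - shift)))
        with pytest.raises(PFTQuantError, match="zero variance"):
            paired_t_logit_dsc(d1, d2)

    def test_power_against_noncentral_t_oracle(self):
        # True logit shift 0.3, sd 0.4, n=20: power from the noncentral t.
        from scipy import stats

        n, shift, sd = 20, 0.3, 0.4
        nc = shift / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        hits = 0
        for rep in range(200):
            g = np.random.default_rng(500 + rep)
            la = g.normal(1.9, sd, n)
            lb = la - shift + g.normal(0, sd, n)  # paired difference N(shift, sd^2)
            hits += paired_t_logit_dsc(1 / (1 + np.exp(-la)), 1 / (1 + np.exp(-lb)))[2] < 0.05
        rate = hits / 200
        assert rate >= 0.60
        assert abs(rate - power) <= 0.10

    def test_null_calibration(self):
        rej = 0
        for rep in range(400):
            g = np.random.default_rng(9000 + rep)
            la, lb = g.normal(1.9, 0.4, 20), g.normal(1.9, 0.4, 20)
            rej += paired_t_logit_dsc(1 / (1 + np.exp(-la)), 1 / (1 + np.exp(-lb)))[2] < 0.05
        assert 0.02 <= rej / 400 <= 0.08


class TestBuildReport:
    def test_self_agreement(self):
        vals = np.array([[10.0, 10.0], [20.0, 20.0], [35.0, 35.0]])
        mask = np.zeros((2, 16, 16), bool)
        mask[0, 2:8, 2:8] = True
        report = build_report(RatingMatrix(vals), [(mask, mask.copy())] * 3)
        assert report.icc.estimate == pytest.approx(1.0)
        assert report.ba.mean_diff == 0.0
        assert (report.dsc_values == 1.0).all()
        assert report.ba.loa[0] <= report.ba.mean_diff <= report.ba.loa[1]

    def test_report_invariants_on_simulated_data(self):
        vals = simulate_rating_table(30, 9, 3, 50, seed=4)
        report = build_report(RatingMatrix(vals))
        assert report.icc.ci95[0] <= report.icc.estimate <= report.icc.ci95[1]
        mid = (report.ba.loa[0] + report.ba.loa[1]) / 2
        assert mid == pytest.approx(report.ba.mean_diff, abs=1e-9)
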