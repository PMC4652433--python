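import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from famrisk.errors import DataError, StatsError
from famrisk.simulate import StudySimConfig, gen_study
from famrisk.stats import (
    AnalysisConfig,
    InstrumentSpec,
    ITEM_COLUMNS,
    analyze_study,
    cronbach_alpha,
    impute_single,
    little_mcar,
    mann_whitney,
    normality_check,
    recode,
    t_test_ind,
    total_score,
)


def items_frame(rows):
    return pd.DataFrame(rows, columns=list(ITEM_COLUMNS))


class TestRecode:
    def test_positive_items_unchanged_negative_reflected(self):
        spec = InstrumentSpec(negative=frozenset({"i02"}))
        frame = items_frame([[3] * 17])
        frame.loc[0, "i02"] = 1
        out = recode(frame, spec)
        assert out.loc[0, "i01"] == 3
        assert out.loc[0, "i02"] == 7  # 8 - 1 on the 7-point scale

    def test_missing_stays_missing(self):
        spec = InstrumentSpec(negative=frozenset({"i05"}))
        frame = items_frame([[4.0] * 17])
        frame.loc[0, "i05"] = np.nan
        assert np.isnan(recode(frame, spec).loc[0, "i05"])

    def test_out_of_range_names_item(self):
        frame = items_frame([[4] * 17])
        frame.loc[0, "i09"] = 9
        with pytest.raises(DataError, match="i09"):
            recode(frame)

    @given(st.lists(st.integers(min_value=1, max_value=7), min_size=17, max_size=17))
    def test_recode_is_an_involution(self, responses):
        spec = InstrumentSpec(negative=frozenset({"i01", "i04", "i17"}))
        frame = items_frame([responses])
        twice = recode(recode(frame, spec), spec)
        assert (twice.to_numpy() == frame.to_numpy(dtype=float)).all()


class TestTotalScore:
    def test_bounds_on_complete_data(self):
        assert total_score(items_frame([[1] * 17])).iloc[0] == 17
        assert total_score(items_frame([[7] * 17])).iloc[0] == 119

    def test_missing_item_gives_missing_total(self):
        frame = items_frame([[5.0] * 17])
        frame.loc[0, "i11"] = np.nan
        assert np.isnan(total_score(frame).iloc[0])


class TestCronbachAlpha:
    def test_perfectly_correlated_two_items(self):
        # two identical items: alpha = 2 * (1 - 2v / 4v) = 1
        x = np.array([[1, 1], [2, 2], [3, 3], [4, 4]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_uncorrelated_two_items(self):
        # sample covariance exactly 0, equal variances: alpha = 0
        x = np.array([[1, 2], [2, 4], [3, 1], [4, 3]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(0.0)

    def test_constant_respondents_undefined(self):
        with pytest.raises(StatsError):
            cronbach_alpha(np.ones((5, 3)))

    def test_invariant_under_consistent_polarity_reversal(self, rng):
        """Reversing an item's wording and recoding it leaves alpha unchanged."""
        base = rng.integers(1, 8, size=(30, 17)).astype(float)
        frame = items_frame(base)
        plain = cronbach_alpha(recode(frame).to_numpy())
        flipped = frame.copy()
        flipped["i03"] = 8 - flipped["i03"]
        spec = InstrumentSpec(negative=frozenset({"i03"}))
        assert cronbach_alpha(recode(flipped, spec).to_numpy()) == pytest.approx(plain)


class TestLittleMCAR:
    def test_complete_matrix_not_applicable(self, rng):
        X = rng.normal(size=(20, 3))
        res = little_mcar(X)
        assert not res.applicable
        assert res.d2 == 0.0 and res.df == 0 and res.n_patterns == 1

    def test_bivariate_monotone_matches_closed_form(self):
        """d2 equals the hand-computed quadratic form at the factored-likelihood
        ML estimates (Anderson closed form for monotone bivariate missingness)."""
        X = np.array(
            [[1.0, 2.0], [2.0, 3.5], [3.0, 3.0], [4.0, 5.5], [6.0, np.nan], [0.5, np.nan]]
        )
        res = little_mcar(X)

        y1 = X[:, 0]
        cc = X[~np.isnan(X[:, 1])]
        mu1, s11 = y1.mean(), y1.var()
        x, y = cc[:, 0], cc[:, 1]
        b1 = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        b0 = y.mean() - b1 * x.mean()
        mu = np.array([mu1, b0 + b1 * mu1])
        s12 = b1 * s11
        s22 = ((y - (b0 + b1 * x)) ** 2).mean() + b1**2 * s11
        sigma = np.array([[s11, s12], [s12, s22]])
        d_cc = cc.mean(axis=0) - mu
        d2_oracle = len(cc) * d_cc @ np.linalg.solve(sigma, d_cc)
        d2_oracle += 2 * (X[4:, 0].mean() - mu1) ** 2 / s11

        assert res.applicable and res.n_patterns == 2
        assert res.df == 1  # (2 + 1) observed-variable slots minus 2 variables
        assert res.d2 == pytest.approx(float(d2_oracle), rel=1e-6)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(d2_oracle, 1)), rel=1e-6)

    def test_null_rejection_rate_near_nominal(self):
        """Under genuinely MCAR normal data the test rejects at ~alpha."""
        rng = np.random.default_rng(7)
        n, p, reps, alpha = 120, 4, 400, 0.05
        cov = 0.4 + 0.6 * np.eye(p)
        chol = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(reps):
            X = rng.standard_normal((n, p)) @ chol.T
            X[rng.random((n, p)) < 0.10] = np.nan
            X = X[~np.isnan(X).all(axis=1)]
            res = little_mcar(X)
            if res.applicable and res.p_value is not None and res.p_value < alpha:
                rejections += 1
        rate = rejections / reps
        band = 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < band


class TestImputeSingle:
    def test_complete_data_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        assert np.array_equal(impute_single(X), X)

    def test_conditional_mean_closed_form(self):
        """A single missing cell is filled with the regression conditional mean."""
        X = np.array(
            [[1.0, 2.0], [2.0, 3.5], [3.0, 3.0], [4.0, 5.5], [6.0, np.nan], [0.5, np.nan]]
        )
        out = impute_single(X)
        cc = X[:4]
        x, y = cc[:, 0], cc[:, 1]
        b1 = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        b0 = y.mean() - b1 * x.mean()
        assert out[4, 1] == pytest.approx(b0 + b1 * X[4, 0], abs=1e-6)
        assert out[5, 1] == pytest.approx(b0 + b1 * X[5, 0], abs=1e-6)

    def test_observed_cells_bit_identical(self, rng):
        X = rng.normal(size=(40, 5))
        X[rng.random((40, 5)) < 0.15] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        out = impute_single(X)
        obs = ~np.isnan(X)
        assert np.array_equal(out[obs], X[obs])
        assert not np.isnan(out).any()

    def test_determinism(self, rng):
        X = rng.normal(size=(30, 4))
        X[rng.random((30, 4)) < 0.1] = np.nan
        assert np.array_equal(impute_single(X), impute_single(X))


class TestTwoGroupTests:
    def test_identical_groups_t_zero_p_one(self):
        res = t_test_ind([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 8.0])
        res = t_test_ind(a, b)
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert res.statistic == pytest.approx(float(t_hand))
        assert res.df == 6

    def test_zero_variance_is_stat_error(self):
        with pytest.raises(StatsError):
            t_test_ind([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])

    def test_shapiro_gate_behaviour(self, rng):
        normal = rng.normal(size=40)
        assert normality_check(normal).p_value > 0.0
        with pytest.raises(StatsError):
            normality_check([1.0, 1.0])

    def test_mann_whitney_minimal_exact_example(self):
        # {1,2} vs {3,4}: U = 0; of the 6 assignments, 2 are as extreme
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.method == "mann_whitney_exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_p_matches_scipy_enumeration(self, rng):
        """Own exact enumeration agrees with scipy's exact method on tie-free
        samples for all group sizes up to 6."""
        for n1, n2 in itertools.product(range(2, 7), repeat=2):
            pooled = rng.permutation(rng.normal(size=n1 + n2))
            a, b = pooled[:n1], pooled[n1:]
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self, rng):
        a = rng.integers(1, 8, size=45).astype(float)
        b = rng.integers(1, 8, size=45).astype(float)
        res = mann_whitney(a, b)
        assert res.method == "mann_whitney_asymptotic"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue))


class TestAnalyzeStudy:
    def test_report_is_fully_populated(self):
        report = analyze_study(gen_study(StudySimConfig(seed=3)))
        d = report.to_dict()
        for section in ("efficiency", "satisfaction"):
            for group in ("diagram", "questionnaire"):
                stats = d[section]["groups"][group]
                assert stats["n"] == 45
                assert np.isfinite(stats["mean"]) and np.isfinite(stats["sd"])
            assert d[section]["selected"] in ("t", "mann_whitney")
            assert 0 <= d[section]["selected_p"] <= 1
        assert d["satisfaction"]["n_participants_missing"] == 21
        assert d["satisfaction"]["mcar"]["applicable"]
        assert 0 < d["satisfaction"]["cronbach_alpha"] < 1

    def test_no_missing_data_skips_mcar_and_imputation(self):
        ds = gen_study(StudySimConfig(seed=4, n_missing_participants=0))
        report = analyze_study(ds)
        assert report.satisfaction.mcar.applicable is False
        assert report.satisfaction.imputed is False
        assert report.satisfaction.n_participants_missing == 0

    def test_normality_gate_selects_nonparametric_iff_shapiro_rejects(self):
        report = analyze_study(gen_study(StudySimConfig(seed=5)))
        for block in (report.efficiency, report.satisfaction):
            rejected = any(t.p_value < 0.05 for t in block.normality.values())
            assert block.selected == ("mann_whitney" if rejected else "t")
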