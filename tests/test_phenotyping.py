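"""Cardiac metrics, cohort bookkeeping and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcct_cardiac.phenotyping import (CardiacRecord, biserial_correlation,
                                      cohen_f, derive_metrics,
                                      derive_metrics_frame,
                                      fit_factorial_model, load_cohort_counts,
                                      lv_volume, make_synthetic_cohort,
                                      posthoc_contrasts, remove_age_outliers,
                                      summarize_cohort)


def _record(**kw):
    base = dict(subject_id="m0", genotype="APOE2", hn=0, sex="M",
                diet="CTRL", age_months=12.0, weight_g=30.0,
                dlvv_ml=0.045, slvv_ml=0.022, hr_bpm=450.0)
    base.update(kw)
    return CardiacRecord(**base)


class TestMetrics:
    def test_lv_volume_3d_arithmetic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask.flat[:1000] = True
        assert lv_volume(mask, 0.125) == pytest.approx(1000 * 0.125**3 / 1000)
        assert lv_volume(np.zeros((4, 4, 4), bool), 0.125) == 0.0

    def test_stroke_volume_from_cohort_group_means(self):
        r = derive_metrics(_record(dlvv_ml=0.045, slvv_ml=0.022))
        assert r.sv_ml == pytest.approx(0.023, abs=1e-12)

    def test_metric_identities(self):
        r = derive_metrics(_record(dlvv_ml=0.05, slvv_ml=0.03, hr_bpm=450.0,
                                   weight_g=40.0))
        assert r.sv_ml == pytest.approx(0.02)
        assert r.ef_pct == pytest.approx(40.0)
        assert r.co_ml_min == pytest.approx(9.0)
        assert r.ci_ml_min_g == pytest.approx(0.225)

    def test_zero_stroke_volume_limits(self):
        r = derive_metrics(_record(dlvv_ml=0.03, slvv_ml=0.03))
        assert r.sv_ml == r.ef_pct == r.co_ml_min == r.ci_ml_min_g == 0.0

    def test_zero_dlvv_rejected(self):
        with pytest.raises(ValueError, match="EF"):
            derive_metrics(_record(dlvv_ml=0.0, slvv_ml=0.0))

    def test_group_mean_linearity_of_stroke_volume(self):
        """mean SV over any subset equals mean DLVV - mean SLVV."""
        df = make_synthetic_cohort(60, seed=3)
        sub = df[df.sex == "Male"]
        assert sub.sv_ml.mean() == pytest.approx(
            sub.dlvv_ml.mean() - sub.slvv_ml.mean(), abs=1e-12)


class TestCohort:
    def test_total_subjects_and_every_percentage(self):
        summ = summarize_cohort(load_cohort_counts())
        assert summ.attrs["total_subjects"] == 123
        by = summ.set_index("isoform")
        assert by.loc["APOE2", ["male", "female"]].tolist() == [17, 10]
        assert by.loc["APOE3", ["male", "female"]].tolist() == [23, 19]
        assert by.loc["APOE4", ["male", "female"]].tolist() == [21, 14]
        assert by.loc["KO", ["male", "female"]].tolist() == [9, 10]
        assert round(by.loc["APOE2", "pct_hn"], 1) == 44.4
        assert round(by.loc["APOE2", "pct_hfd"], 1) == 55.6
        assert round(by.loc["APOE3", "pct_hn"], 1) == 47.6
        assert round(by.loc["APOE3", "pct_hfd"], 1) == 66.7
        assert round(by.loc["APOE4", "pct_hn"], 1) == 57.1
        assert round(by.loc["APOE4", "pct_hfd"], 1) == 51.4
        assert np.isnan(by.loc["KO", "pct_hn"])
        assert round(by.loc["KO", "pct_hfd"], 1) == 52.6

    def test_all_ctrl_cohort_has_zero_pct_hfd(self):
        counts = load_cohort_counts()
        ctrl = counts[counts.diet == "CTRL"]
        summ = summarize_cohort(ctrl)
        assert (summ.pct_hfd == 0).all()


class TestAgeOutliers:
    def _frame(self, ages, genotype="APOE2", sex="Male"):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(ages))],
            "genotype": genotype, "sex": sex, "age_months": ages})

    def test_iqr_rule_drops_extreme_age(self):
        filt, log = remove_age_outliers(self._frame([9, 9, 9, 9, 30]))
        assert len(filt) == 4
        assert log.age_months.tolist() == [30]

    def test_identical_ages_keep_everything(self):
        filt, log = remove_age_outliers(self._frame([12] * 6))
        assert len(filt) == 6 and log.empty

    def test_small_groups_pass_through_with_warning(self):
        with pytest.warns(UserWarning, match="IQR rule skipped"):
            filt, _ = remove_age_outliers(self._frame([9, 40, 41]))
        assert len(filt) == 3

    def test_hn_lines_pool_into_isoform_groups(self):
        df = pd.concat([self._frame([12] * 4, "APOE3"),
                        self._frame([12, 12, 12, 30], "APOE3HN")],
                       ignore_index=True)
        filt, log = remove_age_outliers(df)
        assert len(filt) == 7  # pooled group of 8 drops the age-30 record


class TestFactorialModel:
    def test_single_factor_f_equals_squared_t(self, rng):
        y = np.r_[rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)]
        toy = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12, "y": y})
        fit = fit_factorial_model(toy, "y", formula_rhs="g")
        t, p = stats.ttest_ind(y[:12], y[12:])
        assert fit.anova.F.iloc[0] == pytest.approx(t**2, abs=1e-9)
        assert fit.anova.p.iloc[0] == pytest.approx(p, abs=1e-12)

    def test_constant_response_gives_zero_f(self):
        toy = pd.DataFrame({"g": ["a", "a", "b", "b", "c", "c"],
                            "y": [2.0] * 6})
        fit = fit_factorial_model(toy, "y", formula_rhs="g")
        assert fit.anova.F.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_structural_hn_ko_aliasing_reported(self):
        df = make_synthetic_cohort(120, seed=2)
        fit = fit_factorial_model(df, "co_ml_min")
        assert any("HN:Genotype" in t for t in fit.aliased)

    def test_injected_sex_effect_detected(self):
        df = make_synthetic_cohort(120, seed=5, shifts=[
            dict(column="co_ml_min", where={"sex": "Male"}, delta_sd=2.0)])
        fit = fit_factorial_model(df, "co_ml_min")
        p = float(fit.anova.loc[fit.anova.term == "Sex", "p"].iloc[0])
        assert p < 0.01


@pytest.fixture(scope="module")
def fitted():
    df = make_synthetic_cohort(120, seed=8)
    return fit_factorial_model(df, "co_ml_min",
                               formula_rhs="Sex + Weight + Diet*Genotype")


class TestPosthoc:

    def test_single_pair_adjusted_equals_unadjusted(self, fitted):
        tab = posthoc_contrasts(fitted, "Diet", within={"Genotype": "APOE2"})
        assert len(tab) == 1
        assert tab.p_tukey.iloc[0] == pytest.approx(tab.p_unadj.iloc[0],
                                                    abs=1e-9)

    def test_multi_pair_adjustment_is_monotone(self, fitted):
        tab = posthoc_contrasts(fitted, "Genotype")
        assert len(tab) == 6
        assert (tab.p_tukey >= tab.p_unadj - 1e-12).all()

    def test_confidence_intervals_cover_estimate(self, fitted):
        tab = posthoc_contrasts(fitted, "Genotype")
        assert ((tab.ci_low <= tab.estimate)
                & (tab.estimate <= tab.ci_high)).all()


class TestEffectSizes:
    def test_cohen_f_closed_form_eta2_half(self):
        # two groups, means +-1, no residual noise beyond group structure
        y = np.r_[np.full(10, -1.0), np.full(10, 1.0)]
        y += np.r_[np.linspace(-1, 1, 10), np.linspace(-1, 1, 10)]
        toy = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10, "y": y})
        fit = fit_factorial_model(toy, "y", formula_rhs="g")
        ss_g = float(fit.anova.ss.iloc[0])
        eta2 = ss_g / fit.ss_total
        expect = np.sqrt(eta2 / (1 - eta2))
        assert cohen_f(fit, "g") == pytest.approx(expect, abs=1e-9)

    def test_null_factor_effect_size_is_zero(self):
        toy = pd.DataFrame({"g": ["a", "b"] * 10,
                            "y": np.tile([1.0, 1.0], 10)})
        fit = fit_factorial_model(toy, "y", formula_rhs="g")
        assert cohen_f(fit, "g") == pytest.approx(0.0, abs=1e-9)


class TestBiserial:
    def test_equal_group_means_give_zero(self):
        b = np.r_[np.zeros(10), np.ones(10)]
        w = np.r_[np.arange(10.0), np.arange(10.0)]
        r, _ = biserial_correlation(b, w)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_full_separation_approaches_closed_form(self):
        """For fully separated groups the point-biserial correlation equals
        the value implied by the between/within variance split."""
        n = 40
        b = np.r_[np.zeros(n), np.ones(n)]
        w = np.r_[np.random.default_rng(0).normal(20, 0.01, n),
                  np.random.default_rng(1).normal(50, 0.01, n)]
        r, p = biserial_correlation(b, w)
        assert r == pytest.approx(1.0, abs=1e-3)
        assert p < 1e-50

    def test_diet_weight_association_on_synthetic_cohort(self):
        df = make_synthetic_cohort(123, seed=4)
        r, p = biserial_correlation(df.diet.to_numpy(), df.weight_g.to_numpy())
        assert abs(r) > 0.5 and p < 1e-6

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            biserial_correlation(np.zeros(10), np.arange(10.0))


class TestSyntheticCohort:
    def test_metric_identities_hold_frame_wide(self):
        df = make_synthetic_cohort(80, seed=6)
        assert np.allclose(df.sv_ml, df.dlvv_ml - df.slvv_ml)
        assert np.allclose(df.ef_pct, 100 * df.sv_ml / df.dlvv_ml)
        assert np.allclose(df.co_ml_min, df.sv_ml * df.hr_bpm)
        assert np.allclose(df.ci_ml_min_g, df.co_ml_min / df.weight_g)

    def test_deterministic_given_seed(self):
        a = make_synthetic_cohort(30, seed=9)
        b = make_synthetic_cohort(30, seed=9)
        pd.testing.assert_frame_equal(a, b)
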