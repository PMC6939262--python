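"""Mixed-model machinery: AICc, design building, parameter recovery,
marginal means, correlations and Wald intervals."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from kincare.models import (
    FitResult,
    ModelSpec,
    aicc,
    build_design,
    compare_models,
    confidence_interval,
    fit_lmm,
    marginal_means,
    null_spec,
    pearson,
)
from kincare.pipeline import suite_spec
from kincare.synthetic import SimulationConfig, simulate_dataset


def _dataset(**kw):
    base = dict(seed=0, nests_target=60)
    base.update(kw)
    return simulate_dataset(SimulationConfig(**base))


@pytest.fixture(scope="module")
def default_data():
    return _dataset()


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 5, 200) == pytest.approx(210 + 60 / 194, abs=1e-10)
        assert aicc(0.0, 0, 10) == 0.0

    def test_approaches_aic_for_large_n(self):
        k, ll = 4, -50.0
        aic = -2 * ll + 2 * k
        assert aicc(ll, k, 10**9) == pytest.approx(aic, abs=1e-6)
        assert aicc(ll, k, 30) > aic

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestBuildDesign:
    def test_empty_sessions(self, default_data):
        df = build_design([], default_data.values, null_spec("male_rate"))
        assert df.empty and "rate" in df.columns

    def test_centred_columns_have_zero_mean(self, default_data):
        spec = null_spec("female_rate")
        df = build_design(default_data.sessions, default_data.values, spec)
        assert abs(df["mate_rate"].mean()) < 1e-10
        assert len(df) == len(default_data.sessions)

    def test_unknown_term_rejected(self, default_data):
        spec = null_spec("male_rate").with_terms("not_a_term")
        with pytest.raises(ValueError, match="unknown model term"):
            spec.formula()

    def test_unknown_response_rejected(self, default_data):
        with pytest.raises(ValueError, match="response"):
            build_design(
                default_data.sessions,
                default_data.values,
                ModelSpec(label="x", response="weight"),
            )

    def test_unmatched_nest_raises(self, default_data):
        with pytest.raises(KeyError, match="unknown nest"):
            build_design(default_data.sessions, default_data.values[:1],
                         null_spec("male_rate"))

    def test_sex_specific_columns(self, default_data):
        vals = {v.nest_id: v for v in default_data.values}
        dm = build_design(default_data.sessions, default_data.values, null_spec("male_rate"))
        df = build_design(default_data.sessions, default_data.values, null_spec("female_rate"))
        for k, s in enumerate(default_data.sessions):
            assert dm.loc[k, "tav"] == vals[s.nest_id].TAV_i
            assert df.loc[k, "tav"] == vals[s.nest_id].TAV_j
            assert dm.loc[k, "rate"] == s.male_rate
            assert df.loc[k, "rate"] == df.loc[k, "rate"] == s.female_rate


class TestFit:
    def test_fixed_effects_match_ols_when_random_sds_zero(self):
        # with no grouping variance the ML mixed fit collapses onto OLS
        data = _dataset(
            nests_target=300,
            sessions_per_nest={7: 1.0},
            random_sd={"individual": 0, "mate": 0, "nest": 0, "residual": 1.5},
            effect_sizes={"mate_rate_slope": 0.0},
        )
        spec = suite_spec("TAV", "female_rate")
        design = build_design(data.sessions, data.values, spec)
        assert len(design) >= 1500
        fit = fit_lmm(design, spec)
        X = pd.get_dummies(
            design[["age", "lay_date", "time_of_day", "status", "mate_rate", "tav"]],
            columns=["time_of_day", "status"], drop_first=True, dtype=float)
        X["mate_rate:sec"] = design["mate_rate"] * (design["status"] == "secondary_polygynous")
        X["mate_rate:pri"] = design["mate_rate"] * (design["status"] == "primary_polygynous")
        ols = sm.OLS(design["rate"], sm.add_constant(X)).fit()
        # ML variance components hover just above zero, so agreement is
        # close but not exact
        assert fit.coefficients["tav"][0] == pytest.approx(ols.params["tav"], abs=0.02)
        assert fit.coefficients["age"][0] == pytest.approx(ols.params["age"], abs=0.01)
        assert sum(fit._result.vcomp) < 0.15 * fit._result.scale

    def test_recovers_generating_slopes_within_2se(self):
        eff = {
            "tav_slope_male": 0.9, "lav_slope_male": 0.0, "kij_slope_male": 0.0,
            "mate_rate_slope": 0.0,
        }
        data = _dataset(seed=3, nests_target=200, effect_sizes=eff)
        spec = suite_spec("TAV", "male_rate")
        design = build_design(data.sessions, data.values, spec)
        fit = fit_lmm(design, spec)
        est, se = fit.coefficients["tav"]
        assert fit.converged
        assert abs(est - 0.9) < 2 * se

    def test_constant_response_flagged_degenerate(self, default_data):
        spec = null_spec("male_rate")
        design = build_design(default_data.sessions, default_data.values, spec)
        design["rate"] = 3.0
        fit = fit_lmm(design, spec)
        assert not fit.converged

    def test_parameter_count_bookkeeping(self, default_data):
        spec = null_spec("male_rate")
        design = build_design(default_data.sessions, default_data.values, spec)
        fit = fit_lmm(design, spec)
        # 8 fixed effects (intercept, age, lay_date, afternoon, 2 status,
        # mate_rate, 2 interaction) + 3 variance components + residual
        assert fit.n_params == 9 + 3 + 1
        assert fit.aicc > fit.aic
        assert fit.n_obs == len(design)

    def test_ranking_invariant_to_covariate_rescaling(self, default_data):
        spec = suite_spec("TAV", "male_rate")
        design = build_design(default_data.sessions, default_data.values, spec)
        scaled = design.assign(tav=design["tav"] * 10 + 3)
        f1, f2 = fit_lmm(design, spec), fit_lmm(scaled, spec)
        assert f1.aicc == pytest.approx(f2.aicc, abs=0.05)
        assert f1.coefficients["tav"][0] == pytest.approx(
            10 * f2.coefficients["tav"][0], rel=1e-3
        )


class TestCompare:
    @staticmethod
    def _fake(label, aicc_val, n=100, converged=True):
        return FitResult(
            spec=ModelSpec(label=label, response="male_rate"),
            n_obs=n, n_params=5, loglik=-10.0, aic=aicc_val - 1, aicc=aicc_val,
            coefficients={}, converged=converged,
        )

    def test_identical_models_not_supported(self):
        table = compare_models([self._fake("null", 100.0), self._fake("alt", 100.0)])
        row = table.rows.set_index("label")
        assert row.loc["alt", "delta_aicc"] == 0.0
        assert not row.loc["alt", "supported"]
        assert row.loc["null", "delta_aicc"] == 0.0

    def test_support_threshold(self):
        table = compare_models([self._fake("null", 100.0), self._fake("alt", 97.9)])
        assert table.rows.set_index("label").loc["alt", "supported"].item()
        assert table.delta("alt", "null") == pytest.approx(-2.1)

    def test_mismatched_n_obs_rejected(self):
        with pytest.raises(ValueError, match="different observation counts"):
            compare_models([self._fake("null", 100.0), self._fake("alt", 99.0, n=99)])

    def test_nonconverged_excluded_with_warning(self):
        fits = [self._fake("null", 100.0), self._fake("bad", 90.0, converged=False)]
        with pytest.warns(UserWarning, match="non-converged"):
            table = compare_models(fits)
        assert list(table.rows["label"]) == ["null"]

    def test_nonconverged_null_is_fatal(self):
        fits = [self._fake("null", 100.0, converged=False), self._fake("alt", 99.0)]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="null"):
                compare_models(fits)


class TestMarginalMeans:
    def test_balanced_factor_recovers_group_means(self):
        rng = np.random.default_rng(5)
        n = 80
        tod = np.repeat(["morning", "afternoon"], n // 2)
        y = 4.0 + 2.0 * (tod == "afternoon") + rng.normal(0, 0.3, n)
        design = pd.DataFrame({
            "rate": y, "time_of_day": tod,
            "ind_id": [f"i{k % 8}" for k in range(n)],
            "mate_id": [f"m{k % 7}" for k in range(n)],
            "nest_id": [f"n{k % 10}" for k in range(n)],
        })
        spec = ModelSpec(label="tod", response="male_rate",
                         fixed_terms=("time_of_day",), centering=())
        fit = fit_lmm(design, spec)
        mm = marginal_means(fit, "time_of_day")
        for level in ("morning", "afternoon"):
            assert mm[level][0] == pytest.approx(
                y[tod == level].mean(), abs=3 * mm[level][1] + 0.05
            )
        assert mm["afternoon"][0] - mm["morning"][0] == pytest.approx(2.0, abs=0.3)

    def test_status_shift_recovery(self):
        eff = {
            "status_shifts_male": (0.0, -1.0, -3.0),
            "tav_slope_male": 0.0, "lav_slope_male": 0.0, "kij_slope_male": 0.0,
            "mate_rate_slope": 0.0,
        }
        data = _dataset(seed=11, nests_target=200, effect_sizes=eff)
        spec = null_spec("male_rate")
        design = build_design(data.sessions, data.values, spec)
        fit = fit_lmm(design, spec)
        mm = marginal_means(fit, "status")
        for status, shift in [("primary_polygynous", -1.0), ("secondary_polygynous", -3.0)]:
            diff = mm[status][0] - mm["monogamous"][0]
            se = np.hypot(mm[status][1], mm["monogamous"][1])
            assert abs(diff - shift) < 2 * se

    def test_absent_factor_rejected(self, default_data):
        spec = null_spec("male_rate")
        design = build_design(default_data.sessions, default_data.values, spec)
        fit = fit_lmm(design, spec)
        with pytest.raises(ValueError, match="not among"):
            marginal_means(fit, "bs")


class TestPearson:
    def test_perfect_correlations(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_three_point_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]), ([1, 1, 1], [1, 2, 3])])
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)


class TestConfidenceInterval:
    @staticmethod
    def _fit(est, se):
        return FitResult(
            spec=ModelSpec(label="m", response="male_rate"), n_obs=100, n_params=3,
            loglik=-10, aic=26, aicc=26.3, coefficients={"beta": (est, se)},
            converged=True,
        )

    def test_85pct_wald_interval(self):
        lo, hi = confidence_interval(self._fit(0.12, 0.04), "beta", 0.85)
        # z(0.925) = 1.43953; interval 0.12 +/- 0.05758
        assert (lo, hi) == pytest.approx((0.0624, 0.1776), abs=5e-4)

    def test_zero_se_collapses(self):
        assert confidence_interval(self._fit(1.5, 0.0), "beta", 0.95) == (1.5, 1.5)

    def test_wider_at_higher_level(self):
        f = self._fit(0.12, 0.04)
        lo85, hi85 = confidence_interval(f, "beta", 0.85)
        lo95, hi95 = confidence_interval(f, "beta", 0.95)
        assert lo95 < lo85 < hi85 < hi95

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            confidence_interval(self._fit(0, 1), "gamma", 0.85)
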