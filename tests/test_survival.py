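"""Cox fits under the index codings, spline bases, diagnostics, curves."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methindex.synthetic_data import (
    default_cohort_config,
    default_os_endpoint,
    simulate_cohort,
)
from methindex.survival import (
    ModelSpec,
    adjusted_curves,
    bspline_basis,
    build_design,
    fit_cox,
    fit_spline_cox,
    martingale_diagnostics,
    rcs_basis,
    render_table_text,
    report_tables,
    schoenfeld_test,
)


def two_group_cohort(rate_ratio=2.0, n=4000, seed=1):
    """Exponential two-group toy dressed in the cohort schema.

    Closed-form oracle: under exponential hazards the true HR is the rate
    ratio, so the Cox estimate must recover it within Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    grp = np.repeat([0, 1], n // 2)
    t = rng.exponential(1.0 / np.where(grp == 1, rate_ratio, 1.0))
    return pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(n)],
            "age": 60.0,
            "gender": "male",
            "kps": 80,
            "resection": "biopsy",
            "idh1": 0,
            "index": np.where(grp == 1, 14, 0),
            "os_months": t,
            "os_event": 1,
            "pfs_months": t,
            "pfs_event": 1,
        }
    )


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(default_cohort_config(seed=314))


@pytest.fixture(scope="module")
def tertile_fit(cohort):
    return fit_cox(cohort, ModelSpec(coding="tertile", covariates=("age", "kps", "idh1")))


class TestFitCox:
    def test_exponential_rate_ratio_oracle(self):
        fit = fit_cox(two_group_cohort(), ModelSpec(coding="binary", covariates=()))
        hr = fit.summary.loc["meth_any", "hr"]
        se = fit.summary.loc["meth_any", "se"]
        assert abs(np.log(hr) - np.log(2.0)) < 3 * se
        # both ties conventions agree on this near-tie-free toy
        fit_b = fit_cox(
            two_group_cohort(), ModelSpec(coding="binary", covariates=(), ties="breslow")
        )
        assert fit_b.summary.loc["meth_any", "coef"] == pytest.approx(
            fit.summary.loc["meth_any", "coef"], abs=1e-3
        )

    def test_null_effect_has_unit_hrs_and_half_concordance(self):
        cfg = default_cohort_config(
            seed=6,
            os=default_os_endpoint(effect_mode="null", covariate_log_hrs={}),
        ).scaled(10)
        fit = fit_cox(simulate_cohort(cfg), ModelSpec(coding="tertile", covariates=()))
        for term in fit.meth_terms:
            assert fit.summary.loc[term, "hr"] == pytest.approx(1.0, abs=0.25)
        assert fit.concordance == pytest.approx(0.5, abs=0.03)

    def test_summary_structure_and_global_tests(self, tertile_fit):
        assert list(tertile_fit.meth_terms) == ["meth_1-6", "meth_7-12", "meth_13-17"]
        assert tertile_fit.n == 240
        s = tertile_fit.summary
        assert ((s["ci_lower"] <= s["hr"]) & (s["hr"] <= s["ci_upper"])).all()
        assert (s["hr"] > 0).all()
        for stat, df, p in tertile_fit.global_tests.values():
            assert stat > 0 and df == 6 and 0 <= p <= 1

    def test_time_unit_invariance(self, cohort):
        spec = ModelSpec(coding="tertile", covariates=("age", "kps", "idh1"))
        days = cohort.copy()
        days["os_months"] = days["os_months"] * 30.4375
        a = fit_cox(cohort, spec).summary["hr"]
        b = fit_cox(days, spec).summary["hr"]
        pd.testing.assert_series_equal(a, b, rtol=1e-6)

    def test_continuous_hr_lies_between_extreme_tertile_hrs(self):
        t = simulate_cohort(default_cohort_config(seed=42).scaled(10))
        spec_kw = dict(covariates=("age", "kps", "idh1"))
        tert = fit_cox(t, ModelSpec(coding="tertile", **spec_kw)).summary
        cont = fit_cox(t, ModelSpec(coding="continuous", **spec_kw)).summary
        hrs = tert.loc[["meth_1-6", "meth_7-12", "meth_13-17"], "hr"]
        assert hrs.min() < cont.loc["index", "hr"] ** 8.5 < hrs.max() * 1.5

    def test_too_few_events_rejected(self):
        t = two_group_cohort(n=10)
        t["os_event"] = 0
        t.loc[0, "os_event"] = 1
        with pytest.raises(ValueError, match="events"):
            fit_cox(t, ModelSpec(coding="binary", covariates=()))

    def test_degenerate_level_warns_not_errors(self):
        t = two_group_cohort(n=200)
        t.loc[t["index"] > 0, "os_event"] = 0  # no events among methylated
        fit = fit_cox(t, ModelSpec(coding="binary", covariates=()))
        assert any("zero events" in w for w in fit.warnings)

    def test_constant_covariate_dropped_with_warning(self, cohort):
        t = cohort.copy()
        t["idh1"] = 0
        fit = fit_cox(t, ModelSpec(coding="tertile", covariates=("age", "idh1")))
        assert any("constant" in w for w in fit.warnings)
        assert "idh1" not in fit.summary.index


class TestRcsBasis:
    def test_three_knots_give_two_columns(self):
        B, knots = rcs_basis(np.arange(18.0), n_knots=3)
        assert B.shape == (18, 2) and len(knots) == 3

    def test_linear_beyond_boundary_knots(self):
        x = np.arange(18.0)
        _, knots = rcs_basis(x, n_knots=5)
        grid = np.linspace(knots[-1] + 0.5, knots[-1] + 30.0, 60)
        B, _ = rcs_basis(grid, knots=knots)
        coef = np.ones(B.shape[1])
        second_diff = np.diff(B @ coef, n=2)
        assert np.abs(second_diff).max() < 1e-8

    def test_linear_data_yield_null_nonlinear_terms(self, rng):
        x = rng.uniform(0, 17, 500)
        B, _ = rcs_basis(x, n_knots=5)
        y = 2.0 * x + 1.0
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones_like(x), B]), y, rcond=None
        )
        assert coef[1] == pytest.approx(2.0, abs=1e-8)
        assert np.abs(coef[2:]).max() < 1e-7

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis(np.array([0.0, 0.0, 1.0, 1.0]), n_knots=5)

    def test_heavy_ties_fall_back_to_distinct_value_knots(self, cohort):
        B, knots = rcs_basis(cohort["index"].to_numpy(float), n_knots=5)
        assert np.all(np.diff(knots) > 0)
        assert B.shape[1] == 4

    def test_bspline_partition_of_unity(self):
        x = np.linspace(0, 17, 100)
        B, _ = bspline_basis(x, n_knots=5, drop_first=False)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def shape_cohort():
    cfg = default_cohort_config(
        seed=57, os=default_os_endpoint(effect_mode="spline-shape")
    ).scaled(10)
    return simulate_cohort(cfg)


class TestSplineCox:
    spec = ModelSpec(coding="continuous", covariates=("age", "kps", "idh1", "resection"))

    def test_rcs_curve_reference_and_band(self, shape_cohort):
        sf = fit_spline_cox(shape_cohort, self.spec, basis="rcs")
        at0 = np.argmin(np.abs(sf.grid))
        assert sf.log_hr[at0] == 0.0
        assert (sf.ci_lower <= sf.log_hr).all() and (sf.log_hr <= sf.ci_upper).all()
        assert 8 <= sf.curve_argmin() <= 14

    def test_linear_simulation_shows_no_nonlinearity(self):
        cfg = default_cohort_config(
            seed=70, os=default_os_endpoint(effect_mode="linear")
        ).scaled(10)
        t = simulate_cohort(cfg)
        sf = fit_spline_cox(t, self.spec, basis="rcs")
        assert sf.p_nonlinear > 0.05
        # curve is close to the straight line of the continuous fit
        cont = fit_cox(t, ModelSpec(coding="continuous", covariates=self.spec.covariates))
        line = cont.summary.loc["index", "coef"] * sf.grid
        assert np.abs(sf.log_hr - line).max() < 0.35

    def test_three_bases_agree_on_shape(self, shape_cohort):
        """Segment slope signs (rise to low indices, fall to the trough,
        rise after) agree across RCS, B-spline and P-spline fits."""
        curves = {}
        for basis in ("rcs", "bspline", "pspline"):
            sf = fit_spline_cox(shape_cohort, self.spec, basis=basis)
            f = lambda v, s=sf: s.log_hr[np.argmin(np.abs(s.grid - v))]
            curves[basis] = np.sign(
                [f(4) - f(0.5), f(11) - f(4), f(16.5) - f(11)]
            )
        for basis in ("bspline", "pspline"):
            np.testing.assert_array_equal(curves[basis], curves["rcs"])

    def test_requires_continuous_coding(self, shape_cohort):
        with pytest.raises(ValueError, match="continuous"):
            fit_spline_cox(shape_cohort, ModelSpec(coding="tertile"), basis="rcs")


class TestDiagnostics:
    def test_fitted_model_martingale_residuals_sum_to_zero(self, cohort):
        d = martingale_diagnostics(cohort, unadjusted=False)
        assert abs(d.martingale["residual"].sum()) < 1e-6 * len(cohort)
        assert d.martingale["residual"].max() <= 1.0

    def test_null_model_residuals_sum_to_zero(self, cohort):
        d = martingale_diagnostics(cohort, unadjusted=True)
        assert abs(d.martingale["residual"].sum()) < 1e-8 * len(cohort)

    def test_all_censored_toy_has_nonpositive_residuals(self):
        t = two_group_cohort(n=40)
        t["os_months"] = 10.0
        t["os_event"] = 0
        t.loc[0, "os_event"] = 1  # single event so the hazard is estimable
        d = martingale_diagnostics(t, unadjusted=True)
        assert (d.martingale.loc[1:, "residual"] <= 0).all()

    def test_smoothed_residuals_trough_matches_spline_fit(self, shape_cohort):
        d = martingale_diagnostics(shape_cohort, unadjusted=True)
        s = d.smooth
        trough = s.loc[s["y"].idxmin(), "x"]
        # residual = observed - expected: the protective trough of the hazard
        # (fewer deaths than the average) is the smoothed residuals' minimum,
        # and the excess hazard at low methylation is its positive shoulder
        assert 7 <= trough <= 15
        assert s.loc[(s["x"] >= 1) & (s["x"] <= 6), "y"].mean() > 0
        assert s.loc[(s["x"] >= 9) & (s["x"] <= 13), "y"].mean() < 0

    def test_schoenfeld_on_ph_data_not_significant(self, tertile_fit):
        d = schoenfeld_test(tertile_fit)
        assert set(d.schoenfeld.columns) == {"chi2", "df", "p"}
        assert (d.schoenfeld["df"] == 1).all()
        meth_rows = [r for r in d.schoenfeld.index if str(r).startswith("meth")]
        assert (d.schoenfeld.loc[meth_rows, "p"] > 0.001).all()

    def test_schoenfeld_detects_reversing_effect(self):
        """Piecewise hazards with an effect reversal violate proportionality."""
        rng = np.random.default_rng(15)
        n = 1500
        grp = np.repeat([0, 1], n // 2)
        t_star = 1.0
        # group 1: hazard 3x before t*, 1/3x after
        t0 = rng.exponential(1.0, n)
        t1_first = rng.exponential(1 / 3, n)
        t1_tail = t_star + rng.exponential(3.0, n)
        t = np.where(grp == 0, t0, np.where(t1_first < t_star, t1_first, t1_tail))
        tab = two_group_cohort(n=n)
        tab["os_months"], tab["os_event"] = t, 1
        tab["index"] = np.where(grp == 1, 14, 0)
        fit = fit_cox(tab, ModelSpec(coding="binary", covariates=()))
        d = schoenfeld_test(fit)
        assert d.schoenfeld["p"].iloc[0] < 0.001


class TestAdjustedCurves:
    def test_curves_start_at_one_and_null_curves_coincide(self):
        cfg = default_cohort_config(
            seed=10, os=default_os_endpoint(effect_mode="null", covariate_log_hrs={})
        ).scaled(5)
        fit = fit_cox(simulate_cohort(cfg), ModelSpec(coding="tertile", covariates=()))
        curves = adjusted_curves(fit)
        assert (curves.iloc[0] == 1.0).all()
        spread = (curves.max(axis=1) - curves.min(axis=1)).max()
        assert spread < 0.12

    def test_medium_tertile_dominates_unmethylated(self, tertile_fit):
        """Oracle: the configured medium-tertile hazard is lower, so its
        adjusted survival curve must sit above the unmethylated curve."""
        curves = adjusted_curves(tertile_fit)
        interior = curves.iloc[5:-5]
        assert (interior["7-12"] >= interior["unmethylated"]).mean() > 0.99

    def test_unknown_group_rejected(self, tertile_fit):
        with pytest.raises(ValueError, match="absent"):
            adjusted_curves(tertile_fit, groups=["no-such-level"])


class TestReportTables:
    def test_tertile_block_structure(self, tertile_fit):
        table = report_tables([tertile_fit])
        meth_rows = table[table["variable"].str.startswith("meth_")]
        assert len(meth_rows) == 3
        assert (table["variable"] == "unmethylated (reference)").sum() == 1
        assert {"LR test", "Wald test", "Logrank test"} <= set(table["variable"])
        assert render_table_text(table).lstrip().startswith("model")

    def test_quintile_block_has_five_levels(self, cohort):
        fit = fit_cox(cohort, ModelSpec(coding="quintile", covariates=()))
        table = report_tables([fit])
        assert table["variable"].str.startswith("meth_").sum() == 5

    def test_empty_fit_list_gives_header_only(self):
        table = report_tables([])
        assert table.empty and list(table.columns) == ["model", "variable", "hr", "ci", "p"]
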