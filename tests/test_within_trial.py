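"""Imputation, adjusted incrementals, Rubin pooling, bootstrap, ICER, CEAC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gallstone_cea as g
from gallstone_cea.synthetic import ParameterError
from gallstone_cea.within_trial import (BootstrapDraws, ImputationError,
                                        visit_cols_in)


@pytest.fixture(scope="module")
def mar_cohort(default_params, default_cohort):
    return g.apply_missingness(default_cohort, "MAR",
                               default_params.missing_rate, seed=55)


class TestImputeMissing:
    def test_complete_data_returns_identical_copies(self, small_cohort):
        out = g.impute_missing(small_cohort, m=3, seed=1)
        assert len(out) == 3
        for comp in out:
            pd.testing.assert_frame_equal(comp, small_cohort)

    def test_deterministic_given_seed(self, mar_cohort):
        a = g.impute_missing(mar_cohort, m=2, seed=42)
        b = g.impute_missing(mar_cohort, m=2, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_fills_all_gaps_within_range(self, mar_cohort):
        for comp in g.impute_missing(mar_cohort, m=2, seed=3):
            vals = comp[visit_cols_in(comp)]
            assert vals.notna().all().all()
            assert ((vals >= -0.59) & (vals <= 1.0)).all().all()

    def test_observed_entries_untouched(self, mar_cohort):
        comp = g.impute_missing(mar_cohort, m=2, seed=4)[0]
        for c in visit_cols_in(mar_cohort):
            obs = mar_cohort[c].notna()
            np.testing.assert_allclose(comp.loc[obs, c], mar_cohort.loc[obs, c])

    def test_m_below_two_rejected(self, mar_cohort):
        with pytest.raises(ParameterError):
            g.impute_missing(mar_cohort, m=1, seed=0)

    def test_all_missing_column_rejected(self, small_cohort):
        broken = small_cohort.copy()
        broken["u_24m"] = np.nan
        with pytest.raises(ImputationError, match="u_24m"):
            g.impute_missing(broken, m=2, seed=0)

    def test_agrees_with_statsmodels_mice(self, default_params, unit_costs,
                                          mar_cohort):
        """Pooled incremental QALY from this sampler and from statsmodels
        MICE (PMM) agree within combined Monte-Carlo uncertainty."""
        from statsmodels.imputation.mice import MICEData

        def pooled_dq(completed):
            ests = []
            for comp in completed:
                out = g.cohort_outcomes(comp, unit_costs, default_params)
                fit = g.adjusted_incrementals(comp, out["cost"].to_numpy(),
                                              out["qaly"].to_numpy())
                ests.append((fit.delta_qaly, fit.se_qaly))
            return g.pool_rubin(ests)

        ours, se_ours = pooled_dq(g.impute_missing(mar_cohort, m=10, seed=7))

        cols = (["age", "baseline_utility"] + visit_cols_in(mar_cohort))
        md = mar_cohort[cols].copy()
        md["arm_cm"] = (mar_cohort["arm"] == "CM").astype(float)
        md["sex_m"] = (mar_cohort["sex"] == "M").astype(float)
        np.random.seed(7)
        mice = MICEData(md)
        completed = []
        for _ in range(10):
            mice.update_all(2)
            comp = mar_cohort.copy()
            for c in visit_cols_in(mar_cohort):
                comp[c] = mice.data[c].to_numpy()
            completed.append(comp)
        theirs, se_theirs = pooled_dq(completed)
        assert abs(ours - theirs) < 2 * math.hypot(se_ours, se_theirs)


class TestAdjustedIncrementals:
    def test_identical_outcomes_give_zero_delta(self, small_cohort):
        y = np.full(len(small_cohort), 1.3)
        c = np.full(len(small_cohort), 900.0)
        fit = g.adjusted_incrementals(small_cohort, c, y)
        assert fit.delta_qaly == pytest.approx(0.0, abs=1e-9)
        assert fit.delta_cost == pytest.approx(0.0, abs=1e-6)

    def test_large_n_agrees_with_raw_difference(self, unit_costs):
        p = g.TrialParams(n_per_arm=4000, seed=21)
        coh = g.generate_cohort(p)
        out = g.cohort_outcomes(coh, unit_costs, p)
        fit = g.adjusted_incrementals(coh, out["cost"].to_numpy(),
                                      out["qaly"].to_numpy())
        cm = (coh["arm"] == "CM").to_numpy()
        raw_dc = out["cost"][cm].mean() - out["cost"][~cm].mean()
        raw_dq = out["qaly"][cm].mean() - out["qaly"][~cm].mean()
        assert abs(fit.delta_cost - raw_dc) < 3 * fit.se_cost
        assert abs(fit.delta_qaly - raw_dq) < 3 * fit.se_qaly
        # the optional gamma/log marginal effect agrees at this n too
        fit_g = g.adjusted_incrementals(coh, out["cost"].to_numpy(),
                                        out["qaly"].to_numpy(),
                                        cost_family="gamma-log")
        assert fit_g.cost_model == "gamma-log"
        assert abs(fit_g.delta_cost - raw_dc) < 3 * fit_g.se_cost

    def test_singleton_centre_pooled_with_warning(self, small_cohort):
        data = small_cohort.copy()
        data.loc[data.index[0], "centre"] = 999
        with pytest.warns(UserWarning, match="single participant"):
            fit = g.adjusted_incrementals(
                data, np.random.default_rng(0).gamma(2, 500, len(data)),
                np.random.default_rng(1).normal(1.3, 0.2, len(data)))
        assert np.isfinite(fit.delta_cost)

    def test_gamma_falls_back_on_nonpositive_costs(self, small_cohort):
        cost = np.random.default_rng(2).normal(0, 1, len(small_cohort))
        fit = g.adjusted_incrementals(small_cohort, cost,
                                      np.ones(len(small_cohort)),
                                      cost_family="gamma-log")
        assert fit.cost_model == "linear"


class TestPoolRubin:
    def test_identical_estimates_pass_through(self):
        d, s = g.pool_rubin([(2.5, 0.4)] * 5)
        assert d == pytest.approx(2.5)
        assert s == pytest.approx(0.4)

    def test_hand_computed_between_variance(self):
        d, s = g.pool_rubin([(0.0, 0.0), (2.0, 0.0)])
        assert d == pytest.approx(1.0)
        assert s**2 == pytest.approx((1 + 1 / 2) * 2.0)

    def test_m_below_two_rejected(self):
        with pytest.raises(ParameterError):
            g.pool_rubin([(1.0, 0.1)])

    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(0, 5)),
                    min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_total_variance_at_least_within(self, ests):
        _, s = g.pool_rubin(ests)
        within = np.mean([e[1]**2 for e in ests])
        assert s**2 >= within - 1e-12


class TestComputeIcer:
    def test_sensitivity_row_quotient(self):
        res = g.compute_icer(-1003.0, -0.068)
        assert res.icer == pytest.approx(14750.0, abs=1.0)
        assert res.quadrant == "SW"

    def test_dominant_labelling(self):
        res = g.compute_icer(-100.0, 0.1)
        assert res.quadrant == "dominant"
        assert res.icer == pytest.approx(-1000.0)

    def test_free_gain(self):
        res = g.compute_icer(0.0, 0.1)
        assert res.icer == 0.0
        assert res.quadrant == "dominant"

    def test_zero_qaly_delta_flagged_not_raised(self):
        res = g.compute_icer(500.0, 0.0)
        assert not res.defined
        assert math.isnan(res.icer)
        assert res.quadrant == "undefined"

    def test_dominated(self):
        assert g.compute_icer(100.0, -0.1).quadrant == "dominated"
        assert g.compute_icer(100.0, 0.1).quadrant == "NE"


def _draws(dc, dq, seed=0):
    return BootstrapDraws(np.asarray(dc, dtype=float),
                          np.asarray(dq, dtype=float), seed)


class TestCeacCurve:
    def test_pure_saving_probability_one(self):
        ceac = g.ceac_curve(_draws([-10.0], [0.0]), [0, 13000, 30000])
        assert all(p == 1.0 for p in ceac.values())

    def test_symmetric_cloud_is_half(self):
        ceac = g.ceac_curve(_draws([-5, 5, -5, 5], [0.1, -0.1, -0.1, 0.1]),
                            [0, 20000])
        assert all(p == pytest.approx(0.5) for p in ceac.values())

    def test_sw_cloud_non_increasing_in_lambda(self):
        rng = np.random.default_rng(5)
        dc = -np.abs(rng.normal(1000, 200, 2000))
        dq = -np.abs(rng.normal(0.02, 0.01, 2000))
        ceac = g.ceac_curve(_draws(dc, dq), np.linspace(0, 60000, 25))
        probs = list(ceac.values())
        assert all(b <= a + 1e-12 for a, b in zip(probs, probs[1:]))
        assert probs[0] == 1.0  # all draws are cost-saving

    def test_ceac_at_zero_threshold_is_cost_saving_fraction(self):
        rng = np.random.default_rng(6)
        dc = rng.normal(0, 500, 999)
        dq = rng.normal(0, 0.02, 999)
        ceac = g.ceac_curve(_draws(dc, dq), [0.0])
        assert ceac[0.0] == pytest.approx(np.mean(dc < 0))

    def test_lc_orientation_is_complement(self):
        d = _draws([-100, 200, -50], [0.01, -0.02, 0.0])
        cm = g.ceac_curve(d, [20000], "CM")
        lc = g.ceac_curve(d, [20000], "LC")
        assert cm[20000.0] + lc[20000.0] == pytest.approx(1.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            g.ceac_curve(_draws([], []), [20000])


class TestInb:
    @given(st.floats(-2000, 2000), st.floats(-0.1, 0.1))
    @settings(max_examples=40, deadline=None)
    def test_affine_in_lambda_with_slope_delta_qaly(self, dc, dq):
        lams = [0.0, 10000.0, 20000.0, 40000.0]
        inb = g.inb_curve(dc, dq, lams)
        assert inb[0.0] == pytest.approx(-dc)
        diffs = np.diff([inb[l] for l in lams]) / np.diff(lams)
        assert np.allclose(diffs, dq, atol=1e-9)


class TestBootstrapJoint:
    def test_deterministic(self, small_params, small_cohort, unit_costs):
        kw = dict(params=small_params, costs=unit_costs)
        a = g.bootstrap_joint(small_cohort, B=100, seed=8, **kw)
        b = g.bootstrap_joint(small_cohort, B=100, seed=8, **kw)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_b_too_small_rejected(self, small_cohort, small_params, unit_costs):
        with pytest.raises(ParameterError):
            g.bootstrap_joint(small_cohort, B=50, seed=0,
                              params=small_params, costs=unit_costs)

    def test_draws_are_paired(self, small_params, small_cohort, unit_costs):
        d = g.bootstrap_joint(small_cohort, B=100, seed=9,
                              params=small_params, costs=unit_costs)
        assert len(d.delta_cost) == len(d.delta_qaly) == 100


class TestFullPipeline:
    def test_complete_equals_zero_missingness_path(self, small_params,
                                                   small_cohort, unit_costs):
        """With no missing data the MI layer collapses: both runs agree."""
        r1, _ = g.run_within_trial(small_cohort, small_params, unit_costs,
                                   m=2, B=100, seed=11)
        masked = g.apply_missingness(small_cohort, "MCAR", 0.0, seed=1)
        r2, _ = g.run_within_trial(masked, small_params, unit_costs,
                                   m=2, B=100, seed=11)
        assert r1.estimate.delta_cost == pytest.approx(r2.estimate.delta_cost)
        assert r1.estimate.delta_qaly == pytest.approx(r2.estimate.delta_qaly)

    def test_report_is_fully_populated(self, small_params, small_cohort,
                                       unit_costs):
        res, draws = g.run_within_trial(small_cohort, small_params, unit_costs,
                                        m=2, B=100, seed=12)
        d = res.to_dict()
        for key in ("delta_cost", "delta_qaly", "delta_cost_ci",
                    "delta_qaly_ci", "icer_quadrant", "ceac", "inb"):
            assert d[key] is not None
        assert len(d["ceac"]) == 3
        assert all(0.0 <= p <= 1.0 for p in res.ceac.values())
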