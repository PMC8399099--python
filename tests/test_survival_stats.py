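"""Kaplan-Meier, log-rank and Cox estimators against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from survscreen import (
    cox_fit,
    km_estimate,
    logrank,
    multivariate_fit,
    survival_at,
    univariate_table,
)
from survscreen.exceptions import OneGroupError
from survscreen import GeneEffectSpec, SimConfig, simulate_dataset
from survscreen.screen import gene_indicator

from conftest import ZERO_COVARIATE_EFFECTS
from oracles import naive_km, naive_logrank_chi

# one frozen 20-row dataset; reference coefficients/SEs from R survival::coxph
# (coxph.control(eps=1e-12), ties "efron" and "breslow")
COX_FIXTURE = pd.DataFrame(
    {
        "time": [241, 234, 239, 28, 9, 146, 141, 313, 8, 105,
                 8, 109, 174, 39, 124, 16, 10, 32, 91, 42],
        "event": [1, 1, 0, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1],
        "x1": [0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 0],
        "x2": [-0.866, 0.968, -1.683, -0.335, 0.163, 0.586, 0.711, 0.793, -0.349,
               -0.462, 0.858, -0.191, -1.276, -1.133, -0.919, 0.497, 0.142, 0.69,
               -0.427, 0.159],
    }
)
COX_REFERENCE = {
    "efron": {"coef": [0.4081684520, 0.2211257779], "se": [0.5348723594, 0.2761356370]},
    "breslow": {"coef": [0.4088033144, 0.2202937304], "se": [0.5350381444, 0.2762612784]},
}


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        curve = km_estimate([1, 2, 3], [0, 1, 1])
        assert list(curve.event_times) == [2, 3]
        assert list(curve.survival) == [0.5, 0.0]
        assert survival_at(curve, 1.5) == 1.0
        assert survival_at(curve, 2) == 0.5
        assert survival_at(curve, 99) == 0.0

    def test_censored_only_curve_is_flat_one(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert survival_at(curve, 0) == 1.0
        assert survival_at(curve, 20) == 1.0

    def test_matches_loop_oracle_and_lifelines_on_random_data(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            times = np.ceil(rng.exponential(30, n))
            events = rng.binomial(1, 0.6, n)
            if events.sum() == 0:
                continue
            curve = km_estimate(times, events)
            for (t_ref, s_ref), t_got, s_got in zip(
                naive_km(times, events), curve.event_times, curve.survival
            ):
                assert t_got == t_ref and s_got == pytest.approx(s_ref, abs=1e-12)
            kmf = KaplanMeierFitter().fit(times, events)
            for t, s in zip(curve.event_times, curve.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
                )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1e4), st.integers(0, 1)), min_size=1, max_size=40
        )
    )
    def test_invariants_hold_for_arbitrary_inputs(self, data):
        times = [t for t, _ in data]
        events = [e for _, e in data]
        curve = km_estimate(times, events)
        assert survival_at(curve, 0) <= 1.0
        s = np.concatenate([[1.0], curve.survival])
        assert (np.diff(s) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()
        assert (np.diff(curve.at_risk) < 0).all()  # strictly decreasing


class TestLogrank:
    def test_hand_worked_two_singleton_groups(self):
        res = logrank([1], [1], [2], [1])
        assert res.chi_square == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_give_chi_zero(self):
        t, e = [3, 5, 9], [1, 0, 1]
        res = logrank(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_symmetric_in_group_labels_and_time_scale(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(50, 20), rng.exponential(80, 25)
        ea, eb = rng.binomial(1, 0.8, 20), rng.binomial(1, 0.8, 25)
        res = logrank(ta, ea, tb, eb)
        flipped = logrank(tb, eb, ta, ea)
        assert res.chi_square == pytest.approx(flipped.chi_square, rel=1e-12)
        scaled = logrank(ta * 7.3, ea, tb * 7.3, eb)
        assert res.chi_square == pytest.approx(scaled.chi_square, rel=1e-12)

    def test_matches_direct_formula_and_lifelines_on_random_data(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 50:
            na, nb = int(rng.integers(3, 25)), int(rng.integers(3, 25))
            ta, tb = np.ceil(rng.exponential(40, na)), np.ceil(rng.exponential(60, nb))
            ea, eb = rng.binomial(1, 0.7, na), rng.binomial(1, 0.7, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            try:
                res = logrank(ta, ea, tb, eb)
            except OneGroupError:
                continue
            assert res.chi_square == pytest.approx(
                naive_logrank_chi(ta, ea, tb, eb), abs=1e-10
            )
            ref = logrank_test(ta, tb, ea, eb)
            assert res.p == pytest.approx(ref.p_value, abs=1e-10)
            checked += 1

    def test_no_events_anywhere_is_a_one_group_error(self):
        with pytest.raises(OneGroupError):
            logrank([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxFit:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_frozen_reference_fit(self, ties):
        res = cox_fit(COX_FIXTURE[["x1", "x2"]], COX_FIXTURE["time"], COX_FIXTURE["event"],
                      tie_method=ties)
        assert res.converged
        np.testing.assert_allclose(
            res.summary["coef"], COX_REFERENCE[ties]["coef"], atol=1e-6
        )
        np.testing.assert_allclose(
            res.summary["se"], COX_REFERENCE[ties]["se"], atol=1e-6
        )

    def test_matches_lifelines_on_random_instances(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 50:
            n = int(rng.integers(25, 70))
            X = pd.DataFrame(
                {"x0": rng.binomial(1, 0.5, n).astype(float), "x1": rng.normal(0, 1, n)}
            )
            t = np.ceil(rng.exponential(100, n))
            e = rng.binomial(1, 0.7, n)
            if e.sum() < 3 or X["x0"].nunique() < 2:
                continue
            res = cox_fit(X, t, e)
            if not res.converged:
                continue
            df = X.assign(t=t, e=e)
            cph = CoxPHFitter().fit(df, "t", "e")
            np.testing.assert_allclose(
                res.summary["coef"], cph.params_.to_numpy(), atol=1e-3
            )
            checked += 1

    def test_label_symmetric_data_give_hr_exactly_one(self):
        # two strata with identical time/event patterns
        times = np.array([5, 8, 13, 21, 30, 5, 8, 13, 21, 30], float)
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1, 1])
        group = np.array([0] * 5 + [1] * 5, float)
        res = cox_fit(pd.DataFrame({"g": group}), times, events)
        assert res.hr("g") == pytest.approx(1.0, abs=1e-12)

    def test_recovers_simulated_hazard_ratio(self):
        rng = np.random.default_rng(14)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
        c = rng.exponential(1.0 / 0.0025, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        res = cox_fit(pd.DataFrame({"x": x}), time, event)
        lo, hi = res.ci("x")
        assert lo <= 2.0 <= hi

    def test_mean_log_hr_consistent_over_many_simulations(self):
        rng = np.random.default_rng(15)
        n, true = 1000, np.log(1.8)
        estimates = []
        for _ in range(100):
            x = rng.binomial(1, 0.5, n).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(true * x)))
            c = rng.exponential(1.0 / 0.002, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            res = cox_fit(pd.DataFrame({"x": x}), time, event)
            estimates.append(float(res.summary.loc["x", "coef"]))
        assert abs(np.mean(estimates) - true) <= 0.05

    def test_constant_column_is_one_group_cox(self):
        with pytest.raises(OneGroupError) as exc:
            cox_fit(pd.DataFrame({"x": np.ones(10)}), np.arange(1.0, 11), np.ones(10, int))
        assert exc.value.category == "one-group-cox"

    def test_no_events_rejected(self):
        with pytest.raises(OneGroupError):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1.0, 2.0], [0, 0])


class TestModelTables:
    def test_univariate_table_has_nine_rows(self, medium_cohort):
        dataset, _ = medium_cohort
        groups = pd.Series(
            (dataset.expression.values.iloc[0] > dataset.expression.values.iloc[0].median()),
            index=dataset.patients,
        ).astype(float)
        # covariates were simulated without effects; make them vary but inert
        table, failures = univariate_table(dataset, groups)
        assert len(table) + len(failures) == 9
        assert "gene" in set(table["feature"])

    def test_planted_margin_effect_recovered_in_univariate_row(self):
        cfg = SimConfig(
            n_patients=800,
            n_genes=2,
            baseline_rate=4e-4,
            dropout_rate=2e-4,
            covariate_log_hazards={**ZERO_COVARIATE_EFFECTS, "margin_positive": np.log(2.0)},
            seed=31,
        )
        dataset, _ = simulate_dataset(cfg)
        groups = gene_indicator(
            dataset, "G00001", float(dataset.expression.values.loc["G00001"].median())
        )
        table, _ = univariate_table(dataset, groups)
        row = table.set_index("feature").loc["margin_positive"]
        assert row["ci_low"] <= 2.0 <= row["ci_high"]

    def test_single_level_feature_logged_not_fatal(self, medium_cohort):
        dataset, _ = medium_cohort
        broken = dataset.clinical.copy()
        broken["m1"] = 0
        from survscreen.cohort import AnalysisDataset

        ds = AnalysisDataset(broken, dataset.expression, dataset.profiles)
        groups = gene_indicator(
            ds, "G00002", float(ds.expression.values.loc["G00002"].median())
        )
        table, failures = univariate_table(ds, groups)
        assert {"m1"} == {f["feature"] for f in failures}
        assert len(table) == 8

    def test_multivariate_recovers_gene_and_confounder(self):
        # 95% CIs cover the planted values in a clear majority of replicates
        gene_cover = margin_cover = 0
        for seed in range(32, 38):
            cfg = SimConfig(
                n_patients=1000,
                n_genes=1,
                effects=(GeneEffectSpec("threshold", q=0.5, hr=2.0),),
                baseline_rate=4e-4,
                dropout_rate=2e-4,
                covariate_log_hazards={**ZERO_COVARIATE_EFFECTS, "margin_positive": np.log(1.8)},
                seed=seed,
            )
            dataset, truth = simulate_dataset(cfg)
            groups = pd.Series(
                truth.true_groups.loc["G00001"].to_numpy(float), index=dataset.patients
            )
            res = multivariate_fit(dataset, groups)
            gene_cover += res.ci("gene")[0] <= 2.0 <= res.ci("gene")[1]
            margin_cover += res.ci("margin_positive")[0] <= 1.8 <= res.ci("margin_positive")[1]
        assert gene_cover >= 4 and margin_cover >= 4

    def test_constant_gene_indicator_is_an_error(self, medium_cohort):
        dataset, _ = medium_cohort
        groups = pd.Series(1.0, index=dataset.patients)
        with pytest.raises(OneGroupError):
            multivariate_fit(dataset, groups)

    def test_near_empty_subgroup_flagged(self, medium_cohort):
        dataset, _ = medium_cohort
        clin = dataset.clinical.copy()
        clin["m1"] = 0
        clin.iloc[:3, clin.columns.get_loc("m1")] = 1  # 3 metastatic patients
        from survscreen.cohort import AnalysisDataset

        ds = AnalysisDataset(clin, dataset.expression, dataset.profiles)
        groups = gene_indicator(
            ds, "G00003", float(ds.expression.values.loc["G00003"].median())
        )
        res = multivariate_fit(ds, groups)
        assert any("m1" in w and "near-empty" in w for w in res.warnings)
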