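"""Survival-metric oracles: hand-computed Kaplan-Meier, brute-force
log-rank, partial-likelihood grid search for Cox, rank-sum equivalence of
the time-dependent AUC, 2x2-table accuracy arithmetic, and the NRI worked
example."""

import math

import numpy as np
import pandas as pd
import pytest

from hccmil.simulate import SurvivalSimConfig, generate_survival_cohort
from hccmil.survival import (TimeGrid, continuous_nri, cox_fit, km_estimate,
                             logrank_test, stratify_and_tabulate,
                             time_dependent_accuracy, time_dependent_roc)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        """times (1 censored, 2 event, 3 event): S(2) = 1/2, S(3) = 0."""
        km = km_estimate(pd.DataFrame({"time": [1, 2, 3], "event": [0, 1, 1]}))
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_events_flat_curve(self):
        km = km_estimate(pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]}))
        assert km.survival_at(3) == pytest.approx(1.0)

    def test_reduces_to_empirical_without_censoring(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimate(pd.DataFrame({"time": t, "event": [1, 1, 1, 1]}))
        for i, ti in enumerate(t):
            assert km.survival_at(ti) == pytest.approx(1 - (i + 1) / 4)

    def test_monotone_right_continuous(self):
        coh = generate_survival_cohort(SurvivalSimConfig(n_subjects=200, seed=1))
        km = km_estimate(coh)
        sf = km.survival_function.iloc[:, 0].to_numpy()
        assert np.all(np.diff(sf) <= 1e-12)
        assert km.survival_at(0) == pytest.approx(1.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"time": [0.0, 1.0], "event": [1, 1]}))


def _brute_force_logrank(df):
    """O-E and variance accumulated at each pooled event time (2 groups)."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(df.loc[df.event == 1, "time"].unique()):
        at_risk = df[df.time >= t]
        d = int(((df.time == t) & (df.event == 1)).sum())
        n = len(at_risk)
        n1 = int((at_risk.group == 1).sum())
        d1 = int(((df.time == t) & (df.event == 1) & (df.group == 1)).sum())
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        df = pd.DataFrame({"time": [1, 2, 3] * 2, "event": [1, 0, 1] * 2,
                           "group": [0] * 3 + [1] * 3})
        chi2, dof, p = logrank_test(df)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and dof == 1

    def test_matches_brute_force_oracle_on_six_subjects(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 2.5, 4.0, 5.0],
                           "event": [1, 1, 0, 1, 1, 0],
                           "group": [0, 0, 0, 1, 1, 1]})
        chi2, _, _ = logrank_test(df)
        assert chi2 == pytest.approx(_brute_force_logrank(df), rel=1e-10)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"time": rng.exponential(5, 40) + 0.01,
                           "event": rng.integers(0, 2, 40),
                           "group": rng.integers(0, 2, 40)})
        df.loc[df.event.sum() == 0, "event"] = 1
        a = logrank_test(df)[0]
        df["group"] = 1 - df["group"]
        assert logrank_test(df)[0] == pytest.approx(a, rel=1e-12)

    def test_single_group_raises(self):
        df = pd.DataFrame({"time": [1, 2], "event": [1, 1], "group": [0, 0]})
        with pytest.raises(ValueError):
            logrank_test(df)


def _partial_loglik(beta, time, event, x):
    """Breslow partial log-likelihood for a single covariate, no ties."""
    ll = 0.0
    for i in np.where(event == 1)[0]:
        at_risk = time >= time[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[at_risk]).sum())
    return ll


class TestCox:
    def test_null_recovery(self):
        coh = generate_survival_cohort(SurvivalSimConfig(
            n_subjects=2000, log_hazard_ratios={}, seed=21))
        res = cox_fit(coh, ["marker"])
        assert 0.85 <= res.loc["marker", "hr"] <= 1.18

    def test_parameter_recovery_hr2(self):
        coh = generate_survival_cohort(SurvivalSimConfig(
            n_subjects=2000, log_hazard_ratios={"marker": math.log(2)}, seed=7))
        res = cox_fit(coh, ["marker"])
        assert 1.75 <= res.loc["marker", "hr"] <= 2.3

    def test_matches_grid_search_partial_likelihood(self):
        """Single binary covariate, no ties: the estimate agrees with a
        grid-search maximizer of the hand-coded partial likelihood."""
        rng = np.random.default_rng(3)
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.exp(0.6 * x))
        t = t + rng.uniform(0, 1e-6, n)          # break ties
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x": x})
        res = cox_fit(df, ["x"])
        grid = np.linspace(-1.5, 2.5, 40001)
        ll = [_partial_loglik(b, t, np.ones(n, int), x) for b in grid]
        beta_grid = grid[int(np.argmax(ll))]
        assert res.loc["x", "coef"] == pytest.approx(beta_grid, abs=1e-4)

    def test_location_shift_invariance(self):
        coh = generate_survival_cohort(SurvivalSimConfig(n_subjects=400, seed=5))
        a = cox_fit(coh, ["marker"]).loc["marker", "coef"]
        coh["marker"] = coh["marker"] + 10.0
        b = cox_fit(coh, ["marker"]).loc["marker", "coef"]
        assert a == pytest.approx(b, rel=1e-6)

    def test_scaling_equivariance(self):
        coh = generate_survival_cohort(SurvivalSimConfig(n_subjects=400, seed=5))
        a = cox_fit(coh, ["marker"]).loc["marker", "coef"]
        coh["marker"] = coh["marker"] * 4.0
        b = cox_fit(coh, ["marker"]).loc["marker", "coef"]
        assert b == pytest.approx(a / 4.0, rel=1e-5)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "x": [1, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])


class TestTimeDependentROC:
    def test_perfect_marker_auc_one(self):
        t = np.arange(1.0, 41.0)
        df = pd.DataFrame({"time": t, "event": np.ones(40, int), "m": -t})
        _, auc = time_dependent_roc(df, "m", 20.5)
        assert auc == pytest.approx(1.0)

    def test_matches_rank_sum_oracle_without_censoring(self):
        rng = np.random.default_rng(4)
        n = 120
        t = rng.exponential(10, n)
        m = -t + rng.normal(0, 4, n)
        df = pd.DataFrame({"time": t, "event": np.ones(n, int), "m": m})
        tau = float(np.median(t))
        _, auc = time_dependent_roc(df, "m", tau)
        cases, controls = m[t <= tau], m[t > tau]
        brute = np.mean([(a > b) + 0.5 * (a == b)
                         for a in cases for b in controls])
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        n = 80
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        m = rng.normal(size=n)
        df = pd.DataFrame({"time": t, "event": e, "m": m})
        _, a1 = time_dependent_roc(df, "m", 5.0)
        df["m"] = np.exp(3 * df["m"])
        _, a2 = time_dependent_roc(df, "m", 5.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_marker_auc_half(self):
        rng = np.random.default_rng(6)
        n = 1000
        df = pd.DataFrame({"time": rng.exponential(10, n),
                           "event": np.ones(n, int),
                           "m": rng.normal(size=n)})
        _, auc = time_dependent_roc(df, "m", 8.0)
        assert abs(auc - 0.5) <= 0.05

    def test_agrees_with_scikit_survival_under_censoring(self):
        """Independent cross-check: the IPCW cumulative/dynamic AUC agrees
        with scikit-survival's estimator on a censored cohort."""
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(12)
        n = 400
        m = rng.normal(size=n)
        t = rng.exponential(10, n) * np.exp(-0.7 * m)
        c = rng.exponential(25, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        df = pd.DataFrame({"time": time, "event": event, "m": m})
        tau = float(np.quantile(time, 0.5))
        _, auc = time_dependent_roc(df, "m", tau)
        y = np.array([(bool(e), ti) for e, ti in zip(event, time)],
                     dtype=[("event", bool), ("time", float)])
        ref_auc, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, m, [tau])
        assert auc == pytest.approx(float(ref_auc[0]), abs=0.02)

    def test_no_cases_raises(self):
        df = pd.DataFrame({"time": [10.0, 11.0], "event": [1, 1], "m": [1, 2]})
        with pytest.raises(ValueError):
            time_dependent_roc(df, "m", 1.0)


class TestTimeDependentAccuracy:
    def test_perfect_marker(self):
        t = np.arange(1.0, 21.0)
        df = pd.DataFrame({"time": t, "event": np.ones(20, int), "m": -t})
        res = time_dependent_accuracy(df, "m", 10.5)
        assert res["accuracy"] == pytest.approx(1.0)
        assert res["youden"] == pytest.approx(1.0)

    def test_binary_marker_matches_2x2_table(self):
        """10 subjects, binary marker, no censoring: Se/Sp/accuracy follow
        2x2-table arithmetic at the single non-trivial cutoff."""
        df = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 20, 21, 22, 23, 24.0],
            "event": [1] * 5 + [0] * 5,
            "m": [1, 1, 1, 0, 1, 0, 0, 1, 0, 0],
        })
        # events within tau=10: 5 cases (4 with m=1); controls: 5 (1 with m=1)
        res = time_dependent_accuracy(df, "m", 10.0)
        assert res["sensitivity"] == pytest.approx(4 / 5)
        assert res["specificity"] == pytest.approx(4 / 5)
        assert res["accuracy"] == pytest.approx(0.8 * 0.5 + 0.8 * 0.5)

    def test_independent_marker_cannot_beat_majority(self):
        """A null marker's Youden-point accuracy cannot systematically
        exceed the majority rule max(pi, 1-pi); its Youden index stays at
        noise level."""
        rng = np.random.default_rng(7)
        n = 1500
        df = pd.DataFrame({"time": rng.exponential(10, n),
                           "event": np.ones(n, int), "m": rng.normal(size=n)})
        tau = 3.0
        res = time_dependent_accuracy(df, "m", tau)
        pi = res["prevalence"]
        assert res["accuracy"] <= max(pi, 1 - pi) + 0.05
        assert res["youden"] <= 0.15


class TestContinuousNRI:
    def test_worked_example(self):
        """4 events (3 up, 1 down) and 4 non-events (3 down, 1 up), no
        censoring: NRI = 0.5 + 0.5 = 1.0."""
        df = pd.DataFrame({
            "time": [1, 1, 1, 1, 20, 20, 20, 20.0],
            "event": [1, 1, 1, 1, 0, 0, 0, 0],
            "base": np.zeros(8),
            "new": [1, 1, 1, -1, -1, -1, -1, 1.0],
        })
        res = continuous_nri(df, "base", "new", 10.0, n_bootstrap=50, seed=1)
        assert res["nri"] == pytest.approx(1.0)
        assert res["event_component"] == pytest.approx(0.5)
        assert res["nonevent_component"] == pytest.approx(0.5)

    def test_identical_models_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"time": rng.exponential(10, 50),
                           "event": rng.integers(0, 2, 50),
                           "base": rng.normal(size=50)})
        df["new"] = df["base"]
        res = continuous_nri(df, "base", "new", 5.0, n_bootstrap=20, seed=0)
        assert res["nri"] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"time": rng.exponential(10, 200),
                           "event": np.ones(200, int),
                           "base": rng.normal(size=200),
                           "new": rng.normal(size=200)})
        a = continuous_nri(df, "base", "new", 6.0, n_bootstrap=10, seed=0)
        b = continuous_nri(df, "new", "base", 6.0, n_bootstrap=10, seed=0)
        assert a["nri"] == pytest.approx(-b["nri"], abs=1e-12)

    def test_components_bounded(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"time": rng.exponential(10, 100),
                           "event": rng.integers(0, 2, 100),
                           "base": rng.normal(size=100),
                           "new": rng.normal(size=100)})
        df.loc[0, "event"] = 1
        res = continuous_nri(df, "base", "new", 5.0, n_bootstrap=10, seed=0)
        assert -1 <= res["event_component"] <= 1
        assert -1 <= res["nonevent_component"] <= 1

    def test_noise_marker_ci_covers_zero(self):
        rng = np.random.default_rng(11)
        n = 1000
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "time": np.maximum(rng.exponential(10, n) * np.exp(-0.5 * base), 1e-4),
            "event": np.ones(n, int),
            "base": base,
            "new": base + rng.normal(0, 0.05, n),
        })
        res = continuous_nri(df, "base", "new", 8.0, n_bootstrap=300, seed=2)
        assert res["ci_low"] <= 0.0 <= res["ci_high"]


class TestKMPlot:
    def test_writes_stratified_plot_file(self, tmp_path):
        from hccmil.survival import plot_km

        coh = generate_survival_cohort(SurvivalSimConfig(n_subjects=80, seed=3))
        out = tmp_path / "km.png"
        plot_km(coh, "marker", out)
        assert out.exists() and out.stat().st_size > 1000


class TestTimeGridAndTables:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            TimeGrid((6, 6, 12))
        with pytest.raises(ValueError):
            TimeGrid((-1, 5))

    def test_table_shape_and_determinism(self):
        coh = generate_survival_cohort(SurvivalSimConfig(
            n_subjects=150, censoring_rate=0.2, seed=13))
        coh["noise"] = np.random.default_rng(1).normal(size=len(coh))
        grid = TimeGrid((6.0, 12.0))
        t1 = stratify_and_tabulate(coh, ["true_linear_predictor", "noise"],
                                   grid, n_bootstrap=30, seed=4)
        t2 = stratify_and_tabulate(coh, ["true_linear_predictor", "noise"],
                                   grid, n_bootstrap=30, seed=4)
        assert len(t1) == 4
        pd.testing.assert_frame_equal(t1, t2)

    def test_true_marker_dominates_noise(self):
        coh = generate_survival_cohort(SurvivalSimConfig(
            n_subjects=400, censoring_rate=0.2,
            log_hazard_ratios={"marker": 1.5}, seed=14))
        coh["noise"] = np.random.default_rng(2).normal(size=len(coh))
        grid = TimeGrid((12.0, 24.0))
        t = stratify_and_tabulate(coh, ["marker", "noise"], grid,
                                  n_bootstrap=10, seed=0)
        for tau in grid.times:
            row = t[t.tau == tau]
            assert row[row.marker == "marker"].auc.iloc[0] > \
                row[row.marker == "noise"].auc.iloc[0]
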