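"""Kaplan-Meier and Cox partial-likelihood estimation against independent
oracles: closed-form survival, a hand-written no-ties partial likelihood
maximized on a grid, lifelines, and seeded generative simulations."""

import numpy as np
import pandas as pd
import pytest

from punctasurv.config import GeneratorConfig, GroupSpec
from punctasurv.exceptions import ConvergenceError
from punctasurv.imaging import ROI, Track
from punctasurv.survival import (
    CoxFit,
    build_design,
    build_records,
    cox_fit,
    cox_loglik,
    kaplan_meier,
    lr_test,
    wald_test,
)
from punctasurv.synthetic import sample_cohort, truth_to_records


def geometric_cohort(h_by_group, n, seed, n_timepoints=10):
    """Discrete-time cohort with per-interval hazards by group indicator."""
    rng = np.random.default_rng(seed)
    xs, ts, es = [], [], []
    for x, h in enumerate(h_by_group):
        T = rng.geometric(h, n).astype(float)
        e = T <= n_timepoints
        ts.append(np.minimum(T, n_timepoints) * 24.0)
        es.append(e)
        xs.append(np.full(n, float(x)))
    return (
        np.concatenate(ts),
        np.concatenate(es),
        pd.DataFrame({"x": np.concatenate(xs)}),
    )


# ---------------------------------------------------------------------------
# record construction


def _track(nid, death_interval=None, n=10):
    rois = [
        ROI(0, t, np.zeros((1, 2), int), (0.0, 0.0), 50, 40.0, 8.0, 0.2, 60.0)
        for t in range(n if death_interval is None else death_interval - 1)
    ]
    return Track(
        neuron_id=nid,
        rois=rois,
        death_interval=death_interval,
        censored=death_interval is None,
    )


def test_build_records_times_and_events():
    tracks = [_track("a", 6), _track("b", None)]
    records, excl = build_records(tracks, {"a": True, "b": False}, "CGG")
    assert excl.empty
    rec = records.set_index("neuron_id")
    assert rec.loc["a", "time"] == 144.0 and rec.loc["a", "event"]
    assert rec.loc["b", "time"] == 240.0 and not rec.loc["b", "event"]


def test_build_records_logs_exclusions_and_validates_groups():
    tracks = [_track("a", 4), _track("b", 5)]
    records, excl = build_records(tracks, {"a": False}, "CGG")
    assert len(records) == 1
    assert excl.iloc[0]["neuron_id"] == "b"
    assert excl.iloc[0]["reason"] == "no usable CV"
    with pytest.raises(ValueError, match="unknown group"):
        build_records(tracks, {"a": False, "b": False}, "bad",
                      known_groups=["CGG", "GGN"])


def test_build_design_reference_group_encoding():
    rec = pd.DataFrame(
        {"group": ["a", "b", "c"], "aggregate": [True, False, True]}
    )
    X = build_design(rec, ["group", "aggregate"], reference_group="b")
    assert sorted(X.columns) == ["aggregate", "group[a]", "group[c]"]
    assert X["group[a]"].tolist() == [1.0, 0.0, 0.0]


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_all_censored_is_flat_one():
    km = kaplan_meier([240.0] * 8, [False] * 8)
    assert np.all(km.survival == 1.0)
    assert km.survival_at(240.0) == 1.0


def test_km_product_limit_arithmetic():
    times = [24.0] + [240.0] * 9
    events = [True] + [False] * 9
    km = kaplan_meier(times, events)
    assert km.survival_at(24.0) == pytest.approx(0.9)
    assert km.cumulative_risk[-1] == pytest.approx(0.1)
    assert km.at_risk[1] == 10 and km.events[1] == 1


def test_km_matches_geometric_closed_form():
    cfg = GeneratorConfig(
        seed=13,
        n_neurons_per_group=5000,
        groups=(GroupSpec("g", baseline_hazard_per_interval=0.1),),
    )
    rec = truth_to_records(sample_cohort(cfg), cfg)
    km = kaplan_meier(rec["time"], rec["event"])
    expected = 0.9**10
    se = np.sqrt(expected * (1 - expected) / 5000)
    assert abs(km.survival_at(240.0) - expected) < 3 * se


def test_km_matches_lifelines_exactly():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(3)
    T = np.minimum(rng.geometric(0.15, 300), 10) * 24.0
    E = T < 240.0
    km = kaplan_meier(T, E)
    kmf = KaplanMeierFitter().fit(T, E)
    for t in np.unique(T):
        assert km.survival_at(t) == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
        )


# ---------------------------------------------------------------------------
# Cox: oracles


def naive_partial_loglik(beta, times, events, x):
    """Hand-written Cox partial likelihood for untied data."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def test_six_record_fit_matches_grid_search_oracle():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 0, 1, 1, 0], bool)
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    grid = np.linspace(-3, 3, 60001)
    lls = np.array([naive_partial_loglik(b, times, events, x) for b in grid])
    beta_grid = grid[lls.argmax()]
    fit = cox_fit(times, events, pd.DataFrame({"x": x}))
    assert fit.params["x"] == pytest.approx(beta_grid, abs=1e-4)
    assert fit.loglik == pytest.approx(lls.max(), abs=1e-6)


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(8)
    times = rng.exponential(1.0, 40)
    events = rng.uniform(size=40) < 0.7
    x = rng.normal(size=40)
    fe = cox_fit(times, events, pd.DataFrame({"x": x}), ties="efron")
    fb = cox_fit(times, events, pd.DataFrame({"x": x}), ties="breslow")
    assert fe.params["x"] == fb.params["x"]
    assert fe.loglik == fb.loglik


def test_exchangeable_groups_give_null_hazard_ratio():
    T, E, X = geometric_cohort([0.08, 0.08], 3000, seed=21)
    fit = cox_fit(T, E, X)
    assert abs(fit.params["x"]) < 3 * fit.se["x"]
    assert fit.hazard_ratios["x"] == pytest.approx(1.0, abs=0.2)


def test_fit_matches_lifelines_with_heavy_ties():
    from lifelines import CoxPHFitter

    T, E, X = geometric_cohort([0.05, 0.12], 400, seed=31)
    fit = cox_fit(T, E, X)
    df = X.assign(T=T, E=E)
    cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
    assert fit.params["x"] == pytest.approx(cph.params_["x"], abs=1e-4)
    assert fit.se["x"] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_rank_invariance_under_monotone_time_transform():
    T, E, X = geometric_cohort([0.05, 0.1], 200, seed=5)
    f1 = cox_fit(T, E, X)
    f2 = cox_fit(T**2, E, X)
    assert f1.params["x"] == f2.params["x"]
    assert f1.loglik == f2.loglik


def test_log_partial_likelihood_concave_along_line():
    T, E, X = geometric_cohort([0.05, 0.1], 150, seed=6)
    fit = cox_fit(T, E, X)
    bhat = fit.params.to_numpy()
    lls = [
        cox_loglik(bhat + s, T, E.to_numpy() if hasattr(E, "to_numpy") else E,
                   X.to_numpy())[0]
        for s in np.linspace(-2, 2, 41)
    ]
    second_diff = np.diff(lls, 2)
    assert np.all(second_diff <= 1e-9)


def test_monotone_likelihood_and_degenerate_inputs_raise():
    # monotone likelihood: every event carries the largest covariate in its
    # risk set, so the partial likelihood increases without bound in beta
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.ones(6, bool)
    x = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
    with pytest.raises(ConvergenceError):
        cox_fit(times, events, pd.DataFrame({"x": x}))
    with pytest.raises(ValueError, match="at least one event"):
        cox_fit(times, np.zeros(6, bool), pd.DataFrame({"x": x}))
    with pytest.raises(ValueError, match="collinear"):
        cox_fit(times, events, pd.DataFrame({"a": x, "b": 2 * x}))


# ---------------------------------------------------------------------------
# tests on fits


def test_wald_p_is_one_at_zero_coefficient():
    fit = CoxFit(
        params=pd.Series({"x": 0.0}),
        cov=pd.DataFrame({"x": [0.04]}, index=["x"]),
        loglik=-10.0,
        loglik_null=-10.0,
        n=10,
        n_events=5,
        ties="efron",
        n_iter=1,
        converged=True,
    )
    assert wald_test(fit)["p"]["x"] == pytest.approx(1.0)


def test_lr_test_of_model_against_itself_is_null():
    T, E, X = geometric_cohort([0.05, 0.1], 100, seed=9)
    fit = cox_fit(T, E, X)
    stat, df, p = lr_test(fit, fit)
    assert stat == 0.0 and df == 0 and p == 1.0


def test_lr_test_rejects_non_nested_models():
    T, E, X = geometric_cohort([0.05, 0.1], 100, seed=10)
    f1 = cox_fit(T, E, X.rename(columns={"x": "a"}))
    f2 = cox_fit(T, E, X.rename(columns={"x": "b"}))
    with pytest.raises(ValueError, match="nested"):
        lr_test(f1, f2)


def test_lr_statistic_positive_for_real_effect():
    T, E, X = geometric_cohort([0.04, 0.12], 500, seed=11)
    fit = cox_fit(T, E, X)
    assert fit.lr_statistic > 10
    assert fit.lr_p < 1e-3
    assert fit.loglik >= fit.loglik_null


def test_wald_type_one_error_is_nominal_under_null():
    """Identical planted hazards: Wald p < 0.05 in ~5% of seeded replicates."""
    n_rep, rejections = 1000, 0
    for s in range(n_rep):
        T, E, X = geometric_cohort([0.08, 0.08], 150, seed=50_000 + s)
        fit = cox_fit(T, E, X)
        rejections += fit.wald_p["x"] < 0.05
    rate = rejections / n_rep
    band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < band
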