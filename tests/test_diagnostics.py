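import numpy as np
import pandas as pd
import pytest

import msmcox as mc
from msmcox.diagnostics import (
    dfbetas,
    local_linear_smooth,
    martingale_residuals,
    schoenfeld_scaled,
)
from msmcox.nonparam import nelson_aalen
from msmcox.simulate import illness_death_spec, illness_death_graph, simulate_paths


@pytest.fixture(scope="module")
def small_fit():
    graph = illness_death_graph()
    subjects, _ = simulate_paths(graph, illness_death_spec(), n=30, seed=11)
    episodes = mc.expand_to_episodes(subjects, graph)
    tf = mc.fit_transition_cox(episodes, ("healthy", "ill"), ["treat"])
    return tf, episodes


def test_martingale_residuals_sum_to_zero_and_bounded(id_fit, illness_death):
    tf = id_fit.fits[("healthy", "ill")]
    res = martingale_residuals(tf, illness_death["episodes"])
    r = res.values["residual"]
    assert abs(r.sum()) < 1e-6
    assert (r <= 1.0 + 1e-12).all()
    # censored episode with zero accumulated hazard has residual 0
    first_jump = tf.baseline_times[0]
    early_censored = res.values[
        (illness_death["episodes"]
         .query("from_state == 'healthy' and to_state == 'ill'")
         .reset_index(drop=True)["status"] == 0).to_numpy()
        & (res.values["time"] < first_jump)
    ]
    if len(early_censored):
        assert (early_censored["residual"] == 0).all()


def test_null_model_martingale_closed_form(illness_death):
    """On the null model the residual is the event indicator minus the
    Nelson-Aalen mass over the at-risk interval."""
    fit0 = mc.fit_msm(illness_death["episodes"], illness_death["graph"])
    tf = fit0.fits[("ill", "dead")]
    res = martingale_residuals(tf, illness_death["episodes"])
    eps = illness_death["episodes"]
    rows = eps[(eps["from_state"] == "ill") & (eps["to_state"] == "dead")]
    na = nelson_aalen(eps, ("ill", "dead"))
    expected = rows["status"].to_numpy() - (
        na.cumhaz_at(rows["tstop"]) - na.cumhaz_at(rows["tstart"])
    )
    np.testing.assert_allclose(res.values["residual"], expected, atol=1e-12)


def test_schoenfeld_residuals_sum_to_zero(id_fit, illness_death):
    tf = id_fit.fits[("healthy", "ill")]
    res = schoenfeld_scaled(tf, illness_death["episodes"])
    assert abs(res.extras["unscaled"].sum()) < 1e-6
    assert len(res.values) == tf.n_events  # defined only at event times
    assert "treat" in res.extras["slope_test"]


def test_schoenfeld_zero_when_no_contrast():
    """All covariate values equal: every residual Z - Zbar is exactly 0.

    A constant covariate cannot be fitted (rank deficient), so the fit
    object is built by hand at beta = 0 with the Nelson-Aalen baseline.
    """
    from msmcox.coxmsm import DesignInfo, TransitionCoxFit

    n = 12
    eps = pd.DataFrame(
        {
            "id": range(n), "from_state": ["a"] * n, "to_state": ["b"] * n,
            "trans": [1] * n, "tstart": [0.0] * n,
            "tstop": np.linspace(1, 4, n), "status": [1] * n, "x": [1.0] * n,
        }
    )
    na = nelson_aalen(eps, ("a", "b"))
    design = DesignInfo(covariates=["x"], columns=["x"],
                        categorical={}, column_parent={"x": "x"})
    tf = TransitionCoxFit(
        transition=("a", "b"), design=design, beta=np.zeros(1),
        cov=np.eye(1), loglik=0.0, loglik0=0.0, n_events=n, n_episodes=n,
        baseline_times=na.times, baseline_increments=na.increments,
        ties="breslow", n_iter=0, grad_norm=0.0, means=np.ones(1),
    )
    res = schoenfeld_scaled(tf, eps)
    np.testing.assert_array_equal(res.extras["unscaled"], 0.0)


def test_schoenfeld_detects_reversing_effect():
    """A covariate whose effect reverses sign mid-study violates
    proportional hazards; the scaled-residual slope test must flag it."""
    rng = np.random.default_rng(21)
    n = 1000
    x = rng.integers(0, 2, n).astype(float)
    # piecewise-constant hazard: group 1 at 0.4 before t=3 then 0.05;
    # group 0 constant at 0.15
    t = np.empty(n)
    for i in range(n):
        if x[i] == 0:
            t[i] = rng.exponential(1 / 0.15)
        else:
            t1 = rng.exponential(1 / 0.4)
            t[i] = t1 if t1 < 3.0 else 3.0 + rng.exponential(1 / 0.05)
    cens = np.minimum(t, 25.0)
    status = (t <= 25.0).astype(int)
    eps = pd.DataFrame(
        {
            "id": range(n), "from_state": ["a"] * n, "to_state": ["b"] * n,
            "trans": [1] * n, "tstart": [0.0] * n, "tstop": cens,
            "status": status, "x": x,
        }
    )
    tf = mc.fit_transition_cox(eps, ("a", "b"), ["x"])
    res = schoenfeld_scaled(tf, eps)
    assert res.extras["slope_test"]["x"]["p_value"] < 0.05
    assert res.extras["slope_test"]["x"]["slope"] < 0  # effect fades


def test_dfbetas_approximation_matches_exact_oracle(small_fit):
    tf, episodes = small_fit
    approx = dfbetas(tf, episodes, method="approximate").values["treat"].to_numpy()
    exact = dfbetas(tf, episodes, method="exact").values["treat"].to_numpy()
    close = (np.abs(approx - exact) <= 0.02) | (
        np.abs(approx - exact) <= 0.20 * np.abs(exact)
    )
    assert close.all()
    # the most influential episode per the approximation is (up to near
    # ties) the one whose exact deletion moves the coefficient most
    top = np.argmax(np.abs(approx))
    assert np.abs(exact[top]) >= 0.95 * np.abs(exact).max()


def test_dfbetas_score_method_tracks_exact(small_fit):
    tf, episodes = small_fit
    score = dfbetas(tf, episodes, method="score").values["treat"].to_numpy()
    exact = dfbetas(tf, episodes, method="exact").values["treat"].to_numpy()
    assert np.corrcoef(score, exact)[0, 1] > 0.95


def test_dfbetas_shrink_on_duplicated_data():
    """Duplicating a balanced dataset halves every episode's leverage."""
    n = 10
    rng = np.random.default_rng(3)
    base = pd.DataFrame(
        {
            "id": range(n), "from_state": ["a"] * n, "to_state": ["b"] * n,
            "trans": [1] * n, "tstart": [0.0] * n,
            "tstop": rng.exponential(5.0, n) + 0.1,
            "status": [1] * n, "x": rng.normal(size=n),
        }
    )
    dup = base.copy()
    dup["id"] = dup["id"] + 100
    both = pd.concat([base, dup], ignore_index=True)
    tf1 = mc.fit_transition_cox(base, ("a", "b"), ["x"])
    tf2 = mc.fit_transition_cox(both, ("a", "b"), ["x"])
    d1 = np.abs(dfbetas(tf1, base, "exact").values["x"]).max()
    d2 = np.abs(dfbetas(tf2, both, "exact").values["x"]).max()
    assert d2 < d1


def test_dfbetas_exact_cap(small_fit):
    tf, episodes = small_fit
    with pytest.raises(Exception, match="cap"):
        dfbetas(tf, episodes, method="exact", exact_cap=5)


def test_local_linear_smoother_recovers_line():
    rng = np.random.default_rng(1)
    x = np.linspace(0, 10, 80)
    y = 2.0 + 0.5 * x + rng.normal(0, 0.05, 80)
    sm = local_linear_smooth(x, y, span=0.5)
    np.testing.assert_allclose(sm["fit"], 2.0 + 0.5 * sm["x"], atol=0.1)
    assert (sm["se"] > 0).all()
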