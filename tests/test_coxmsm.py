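import numpy as np
import pandas as pd
import pytest

import msmcox as mc
from msmcox.coxmsm import (
    CoxError,
    aic,
    fit_msm,
    fit_transition_cox,
    gof_tests,
    hazard_ratio_table,
)
from msmcox.nonparam import nelson_aalen
from msmcox.simulate import illness_death_graph, illness_death_spec, simulate_paths


def test_null_fit_baseline_is_nelson_aalen(illness_death):
    """With no covariates the Breslow baseline must reduce to the
    Nelson-Aalen estimator exactly."""
    fit = fit_msm(illness_death["episodes"], illness_death["graph"])
    for trans, tf in fit.fits.items():
        na = nelson_aalen(illness_death["episodes"], trans)
        np.testing.assert_array_equal(tf.baseline_times, na.times)
        np.testing.assert_allclose(tf.baseline_increments, na.increments, atol=1e-14)
        assert tf.loglik == tf.loglik0


def test_parameter_recovery_within_three_se(illness_death):
    tf = fit_transition_cox(illness_death["episodes"], ("healthy", "ill"), ["treat"])
    assert abs(tf.beta[0] - np.log(2.0)) < 3.0 * tf.se[0]
    assert tf.grad_norm < 1e-6
    assert tf.cov[0, 0] > 0


def test_duplicating_episodes_leaves_beta_unchanged(illness_death):
    eps = illness_death["episodes"]
    sub = eps[(eps["from_state"] == "healthy") & (eps["to_state"] == "ill")].head(10)
    # give the duplicates fresh ids so no invariants are violated
    dup = sub.copy()
    dup["id"] = dup["id"] + 10_000
    tf1 = fit_transition_cox(sub, ("healthy", "ill"), ["treat"])
    tf2 = fit_transition_cox(pd.concat([sub, dup]), ("healthy", "ill"), ["treat"])
    np.testing.assert_allclose(tf1.beta, tf2.beta, atol=1e-8)


def test_agrees_with_independent_implementation(illness_death):
    """Single-transition, right-censored episodes: coefficients must match
    an established Cox implementation to 1e-4."""
    from lifelines import CoxPHFitter

    eps = illness_death["episodes"]
    rows = eps[(eps["from_state"] == "healthy") & (eps["to_state"] == "ill")]
    tf = fit_transition_cox(eps, ("healthy", "ill"), ["treat"])
    df = pd.DataFrame(
        {"T": rows["tstop"], "E": rows["status"], "treat": rows["treat"]}
    )
    cph = CoxPHFitter().fit(df, "T", "E")
    assert abs(float(cph.params_.iloc[0]) - tf.beta[0]) < 1e-4
    assert abs(float(cph.standard_errors_.iloc[0]) - tf.se[0]) < 1e-4


def test_efron_close_to_breslow_without_ties(illness_death):
    b = fit_transition_cox(illness_death["episodes"], ("healthy", "ill"), ["treat"],
                           ties="breslow")
    e = fit_transition_cox(illness_death["episodes"], ("healthy", "ill"), ["treat"],
                           ties="efron")
    # continuous event times: the two tie conventions coincide
    np.testing.assert_allclose(b.beta, e.beta, atol=1e-8)


def test_zero_event_transition_refused_and_reported():
    g = illness_death_graph()
    eps = pd.DataFrame(
        {
            "id": [1, 1], "from_state": ["healthy"] * 2,
            "to_state": ["ill", "dead"], "trans": [1, 2],
            "tstart": [0.0, 0.0], "tstop": [5.0, 5.0], "status": [1, 0],
        }
    )
    with pytest.raises(CoxError, match="healthy -> dead"):
        fit_transition_cox(eps, ("healthy", "dead"))
    fit = fit_msm(eps, g)
    assert ("healthy", "dead") in fit.unfit
    assert ("ill", "dead") in fit.unfit


def test_collinear_design_rejected(illness_death):
    eps = illness_death["episodes"].copy()
    eps["treat2"] = eps["treat"] * 2.0
    with pytest.raises(CoxError, match="collinear"):
        fit_transition_cox(eps, ("healthy", "ill"), ["treat", "treat2"])


def test_monotone_likelihood_detected():
    # covariate perfectly separates events from censorings
    n = 40
    eps = pd.DataFrame(
        {
            "id": range(n), "from_state": ["a"] * n, "to_state": ["b"] * n,
            "trans": [1] * n, "tstart": [0.0] * n,
            "tstop": np.linspace(1, 5, n),
            "status": [1] * (n // 2) + [0] * (n // 2),
            "x": [1.0] * (n // 2) + [0.0] * (n // 2),
        }
    )
    with pytest.raises(CoxError, match="separate|converge"):
        fit_transition_cox(eps, ("a", "b"), ["x"])


def test_likelihood_factorizes_over_transitions(illness_death):
    eps = illness_death["episodes"]
    joint = fit_msm(eps, illness_death["graph"], {("healthy", "ill"): ["treat"]})
    sep = fit_transition_cox(eps, ("healthy", "ill"), ["treat"])
    np.testing.assert_allclose(joint.fits[("healthy", "ill")].beta, sep.beta)
    assert joint.total_loglik == pytest.approx(
        sum(f.loglik for f in joint.fits.values())
    )


def test_null_assignment_matches_null_loglik(illness_death):
    fit = fit_msm(illness_death["episodes"], illness_death["graph"])
    assert fit.total_loglik == fit.total_loglik0


def test_hazard_ratio_table_closed_forms(id_fit):
    tbl = hazard_ratio_table(id_fit, level=0.95)
    row = tbl[tbl["covariate"] == "treat"].iloc[0]
    tf = id_fit.fits[("healthy", "ill")]
    z = 1.959963984540054
    assert row["HR"] == pytest.approx(np.exp(tf.beta[0]))
    assert row["ci_low"] == pytest.approx(np.exp(tf.beta[0] - z * tf.se[0]))
    assert row["ci_high"] == pytest.approx(np.exp(tf.beta[0] + z * tf.se[0]))
    # rescaling: HR per 10 units is exp(10 beta); p-value unchanged
    tbl10 = hazard_ratio_table(id_fit, scale={"treat": 10.0})
    row10 = tbl10[tbl10["covariate"] == "treat"].iloc[0]
    assert row10["HR"] == pytest.approx(np.exp(10.0 * tf.beta[0]))
    assert row10["p_value"] == pytest.approx(row["p_value"])
    with pytest.raises(CoxError, match="unknown covariate"):
        hazard_ratio_table(id_fit, scale={"nope": 2.0})


def test_gof_three_tests_agree_and_reject_large_effect(id_fit):
    g = gof_tests(id_fit.fits[("healthy", "ill")])
    assert set(g["test"]) == {"likelihood ratio", "wald", "score"}
    assert (g["df"] == 1).all()
    # true log HR = ln 2 with ~350 events: all three far beyond the 5%
    # chi-square(1) critical value
    assert (g["statistic"] > 3.841).all()
    spread = g["p_value"].max() - g["p_value"].min()
    assert spread < 0.05


def test_gof_null_model_empty(illness_death):
    fit0 = fit_msm(illness_death["episodes"], illness_death["graph"])
    g = gof_tests(fit0.fits[("healthy", "ill")])
    assert len(g) == 0
    assert "null" in g.attrs["note"]


def test_aic_identities(illness_death, id_fit):
    fit0 = fit_msm(illness_death["episodes"], illness_death["graph"])
    a0 = aic(fit0)
    np.testing.assert_allclose(a0["AIC"], -2.0 * a0["loglik"])
    a1 = aic(id_fit)
    assert a1.attrs["total_AIC"] == pytest.approx(a1["AIC"].sum())
    # adding one covariate changes that transition's AIC by 2 - LRT
    tf = id_fit.fits[("healthy", "ill")]
    lrt = 2.0 * (tf.loglik - tf.loglik0)
    aic_null = -2.0 * tf.loglik0
    aic_fit = -2.0 * tf.loglik + 2.0
    assert aic_fit - aic_null == pytest.approx(2.0 - lrt)


def test_categorical_covariate_reference_coding():
    g = mc.build_graph(["a", "b"], [("a", "b")])
    rng = np.random.default_rng(5)
    n = 200
    grp = rng.choice(["lo", "mid", "hi"], size=n)
    rate = np.where(grp == "hi", 0.3, 0.1)
    t = rng.exponential(1.0 / rate)
    eps = pd.DataFrame(
        {
            "id": range(n), "from_state": ["a"] * n, "to_state": ["b"] * n,
            "trans": [1] * n, "tstart": [0.0] * n, "tstop": t,
            "status": [1] * n, "grp": grp,
        }
    )
    tf = fit_transition_cox(eps, ("a", "b"), ["grp"])
    # sorted levels: hi, lo, mid -> reference "hi", columns grp[lo], grp[mid]
    assert tf.columns == ["grp[lo]", "grp[mid]"]
    assert tf.beta[0] < 0  # lo has a lower hazard than the reference hi


def test_fit_bundle_round_trip(id_fit):
    d = id_fit.to_dict()
    back = mc.MsmFit.from_dict(d)
    for trans, tf in id_fit.fits.items():
        np.testing.assert_array_equal(back.fits[trans].beta, tf.beta)
        np.testing.assert_array_equal(
            back.fits[trans].baseline_increments, tf.baseline_increments
        )
    assert back.total_aic == id_fit.total_aic
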