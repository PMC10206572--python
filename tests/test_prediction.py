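import warnings

import numpy as np
import pandas as pd
import pytest

import msmcox as mc
from msmcox.nonparam import nelson_aalen
from msmcox.prediction import (
    Profile,
    aalen_johansen,
    most_likely_state,
    occupancy,
    profile_hazards,
)


def test_null_fit_profile_hazards_equal_nelson_aalen(illness_death):
    fit0 = mc.fit_msm(illness_death["episodes"], illness_death["graph"])
    hz = profile_hazards(fit0, Profile({}, "healthy"))
    for trans, (t, dh) in hz.items():
        na = nelson_aalen(illness_death["episodes"], trans)
        np.testing.assert_array_equal(t, na.times)
        np.testing.assert_allclose(dh, na.increments, atol=1e-14)


def test_profile_multiplies_hazard_by_exp_beta(id_fit):
    tf = id_fit.fits[("healthy", "ill")]
    h0 = profile_hazards(id_fit, Profile({"treat": 0}, "healthy"))
    h1 = profile_hazards(id_fit, Profile({"treat": 1}, "healthy"))
    ratio = h1[("healthy", "ill")][1] / h0[("healthy", "ill")][1]
    np.testing.assert_allclose(ratio, np.exp(tf.beta[0]))
    # unmodelled transitions are profile-independent
    np.testing.assert_array_equal(h0[("ill", "dead")][1], h1[("ill", "dead")][1])


def test_missing_profile_covariate_rejected(id_fit):
    with pytest.raises(Exception, match="treat"):
        occupancy(id_fit, Profile({}, "healthy"), horizon=10.0)


def test_rows_sum_to_one_and_identity_at_origin(id_fit):
    hz = profile_hazards(id_fit, Profile({"treat": 1}, "healthy"))
    tpm = aalen_johansen(hz, id_fit.graph)
    np.testing.assert_allclose(tpm.matrices.sum(axis=2), 1.0, atol=1e-9)
    assert (tpm.matrices >= -1e-12).all()
    np.testing.assert_array_equal(tpm.matrices[0], np.eye(3))
    # absorbing rows are unit vectors at all times
    np.testing.assert_allclose(tpm.matrices[:, 2, 2], 1.0)


def test_chapman_kolmogorov_on_jump_grid(id_fit):
    hz = profile_hazards(id_fit, Profile({"treat": 0}, "healthy"))
    t1 = 8.0
    full = aalen_johansen(hz, id_fit.graph, t0=0.0)
    first = aalen_johansen(hz, id_fit.graph, t0=0.0, t_grid=[t1])
    second = aalen_johansen(hz, id_fit.graph, t0=t1)
    for t2 in [12.0, 20.0, 29.0]:
        lhs = full.at(t2)
        rhs = first.at(t1) @ second.at(t2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_no_events_in_window_gives_identity(id_fit):
    hz = profile_hazards(id_fit, Profile({"treat": 0}, "healthy"))
    last = max(t[-1] for t, _ in hz.values() if len(t))
    tpm = aalen_johansen(hz, id_fit.graph, t0=last + 1.0)
    np.testing.assert_array_equal(tpm.matrices[-1], np.eye(3))


def test_two_state_p11_equals_kaplan_meier(two_state):
    """P_11(0, t) from the product integral equals the Kaplan-Meier
    survival curve at every event time (independent implementation)."""
    from lifelines import KaplanMeierFitter

    eps = two_state["episodes"]
    na = nelson_aalen(eps, ("alive", "dead"))
    tpm = aalen_johansen(
        {("alive", "dead"): (na.times, na.increments)}, two_state["graph"]
    )
    km = KaplanMeierFitter().fit(eps["tstop"], eps["status"])
    km_vals = km.survival_function_at_times(tpm.times).to_numpy()
    np.testing.assert_allclose(tpm.matrices[:, 0, 0], km_vals, atol=1e-12)


def test_overunit_jump_mass_clamped_with_warning():
    g = mc.build_graph(["a", "b", "c"], [("a", "b"), ("a", "c")])
    hz = {
        ("a", "b"): (np.array([1.0]), np.array([0.9])),
        ("a", "c"): (np.array([1.0]), np.array([0.6])),
    }
    with pytest.warns(UserWarning, match="rescaled"):
        tpm = aalen_johansen(hz, g)
    row = tpm.matrices[-1][0]
    np.testing.assert_allclose(row.sum(), 1.0)
    assert row[0] == 0.0
    assert row[1] == pytest.approx(0.9 / 1.5)


def test_occupancy_summary_and_monotone_death(id_fit):
    prof = Profile({"treat": 1}, "healthy")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occ = occupancy(id_fit, prof, horizon=25.0)
    assert occ.at_horizon.sum() == pytest.approx(1.0, abs=1e-9)
    dead = occ.curves["dead"].to_numpy()
    assert (np.diff(dead) >= -1e-12).all()  # absorbing occupancy nondecreasing
    assert occ.most_likely_state in id_fit.graph.states
    # beyond the last event the curve is held constant and flagged
    with pytest.warns(UserWarning, match="held constant"):
        far = occupancy(id_fit, prof, horizon=1000.0)
    assert far.extrapolated
    np.testing.assert_allclose(
        far.at_horizon.to_numpy(), far.curves.iloc[-1, 1:].to_numpy(dtype=float)
    )


def test_most_likely_state_tie_break():
    assert most_likely_state(pd.Series([0.1, 0.2, 0.7], index=list("abc"))) == "c"
    assert most_likely_state(pd.Series([0.5, 0.5], index=list("ab"))) == "a"
    # invariant under strictly monotone transforms
    s = pd.Series([0.2, 0.5, 0.3], index=list("abc"))
    assert most_likely_state(s) == most_likely_state(np.sqrt(s))


def test_occupancy_matches_monte_carlo(illness_death):
    """Predicted occupancy for a fixed profile agrees with the empirical
    state distribution of fresh simulated subjects sharing that profile."""
    from msmcox.simulate import simulate_paths, illness_death_graph
    from msmcox.data_model import subject_paths
    import dataclasses

    g = illness_death_graph()
    spec = illness_death["spec"]
    # force everyone to the treat=1 profile
    spec1 = dataclasses.replace(
        spec, covariates={"treat": mc.CovariateSpec("binary", p=1.0)}
    )
    subs, _ = simulate_paths(g, spec1, n=4000, seed=909)
    paths = subject_paths(subs, g)
    tau = 10.0
    freq = pd.Series(0.0, index=list(g.states))
    for p in paths:
        freq[p.state_at(tau)] += 1
    freq /= len(paths)

    fit = mc.fit_msm(
        illness_death["episodes"], g, {("healthy", "ill"): ["treat"]}
    )
    occ = occupancy(fit, Profile({"treat": 1}, "healthy"), horizon=tau)
    assert np.max(np.abs(occ.at_horizon - freq)) < 0.03
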