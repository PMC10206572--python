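"""Non-parametric estimation: Nelson-Aalen cumulative transition
intensities, kernel-smoothed instantaneous hazards (optionally stratified by
a categorical covariate), and cumulative incidence of absorbing states.

The Nelson-Aalen estimator for transition ``k -> l`` jumps at each observed
``k -> l`` event time ``t_j`` by ``dN_kl(t_j) / Y_k(t_j)``, where ``dN`` is
the number of events at ``t_j`` (tied events aggregated, consistent with
Breslow tie handling in the Cox module) and ``Y_k`` the number of subjects
occupying state ``k`` just before ``t_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_graph import StateGraph

__all__ = [
    "HazardEstimate",
    "nelson_aalen",
    "smoothed_hazard",
    "smoothed_hazard_stratified",
    "cumulative_incidence",
]


@dataclass
class HazardEstimate:
    """Step-function estimate of one cumulative transition intensity."""

    transition: tuple[str, str]
    times: np.ndarray        # ordered jump times t_1 < ... < t_J
    increments: np.ndarray   # dN_kl(t_j) / Y_k(t_j)
    at_risk: np.ndarray      # Y_k(t_j)
    n_events: np.ndarray     # dN_kl(t_j)
    window: tuple[float, float]  # observed time window [t_min, t_max]

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def cumhaz_at(self, t) -> np.ndarray:
        """Right-continuous evaluation of the cumulative hazard."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


def nelson_aalen(episodes: pd.DataFrame, transition: tuple[str, str]) -> HazardEstimate:
    """Nelson-Aalen estimate for one transition from the episode table.

    The risk set uses only this transition's rows: every subject at risk in
    the origin state contributes one episode row per competing transition
    with the shared at-risk interval, so those rows carry the full risk
    information for the origin state.
    """
    k, l = transition
    rows = episodes[(episodes["from_state"] == k) & (episodes["to_state"] == l)]
    tmax = float(episodes["tstop"].max()) if len(episodes) else 0.0
    if not len(rows) or not rows["status"].any():
        return HazardEstimate(
            transition=(k, l), times=np.array([]), increments=np.array([]),
            at_risk=np.array([]), n_events=np.array([]), window=(0.0, tmax),
        )
    tstart = rows["tstart"].to_numpy(dtype=float)
    tstop = rows["tstop"].to_numpy(dtype=float)
    status = rows["status"].to_numpy()
    ev = tstop[status == 1]
    times, counts = np.unique(ev, return_counts=True)
    # Y_k(t) = number of intervals with tstart < t <= tstop
    at_risk = np.array(
        [int(np.sum((tstart < t) & (t <= tstop))) for t in times], dtype=float
    )
    if np.any(at_risk < counts):
        raise RuntimeError(
            f"internal error: fewer subjects at risk than events for {k} -> {l}"
        )
    return HazardEstimate(
        transition=(k, l),
        times=times,
        increments=counts / at_risk,
        at_risk=at_risk,
        n_events=counts.astype(float),
        window=(0.0, tmax),
    )


def _epanechnikov_mass(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Integral of the Epanechnikov kernel over [lo, hi] within [-1, 1]."""
    lo = np.clip(lo, -1.0, 1.0)
    hi = np.clip(hi, -1.0, 1.0)
    F = lambda x: 0.75 * (x - x**3 / 3.0) + 0.5
    return F(hi) - F(lo)


def smoothed_hazard(
    estimate: HazardEstimate,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kernel-smoothed instantaneous hazard from Nelson-Aalen increments.

    Epanechnikov kernel; default bandwidth is one eighth of the observed
    window; near the window boundaries the kernel mass falling inside the
    window is renormalized so the curve integrates approximately to the
    total cumulative hazard.  Returns a tidy frame (time, hazard).
    """
    tmin, tmax = estimate.window
    if bandwidth is None:
        bandwidth = (tmax - tmin) / 8.0 if tmax > tmin else 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        grid = np.linspace(tmin, tmax, 101)
    grid = np.asarray(grid, dtype=float)
    if not len(estimate.times):
        return pd.DataFrame({"time": grid, "hazard": np.zeros_like(grid)})
    u = (grid[:, None] - estimate.times[None, :]) / bandwidth
    kern = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0) / bandwidth
    raw = kern @ estimate.increments
    mass = _epanechnikov_mass((tmin - grid) / bandwidth, (tmax - grid) / bandwidth)
    mass = np.where(mass > 1e-12, mass, 1.0)
    return pd.DataFrame({"time": grid, "hazard": raw / mass})


def smoothed_hazard_stratified(
    episodes: pd.DataFrame,
    transition: tuple[str, str],
    covariate: str,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> dict:
    """Per-level smoothed hazard curves, stratifying episodes by a
    categorical covariate.  Equivalent to filtering then estimating."""
    if covariate not in episodes.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    out = {}
    for level, sub in episodes.groupby(covariate, sort=True):
        est = nelson_aalen(sub, transition)
        if not len(est.times):
            warnings.warn(
                f"stratum {covariate}={level!r} has no {transition[0]} -> "
                f"{transition[1]} events; empty curve"
            )
        out[level] = smoothed_hazard(est, bandwidth=bandwidth, grid=grid)
    return out


def cumulative_incidence(
    episodes: pd.DataFrame, graph: StateGraph, absorbing_state: str
) -> pd.DataFrame:
    """Occupancy probability of an absorbing state over time.

    Aalen-Johansen product integral over the pooled Nelson-Aalen
    increments, started from the empirical distribution of states occupied
    at time 0.  Returns a tidy frame (time, probability), nondecreasing and
    within [0, 1].
    """
    from .prediction import aalen_johansen  # late import: avoids cycle

    if graph.roles.get(absorbing_state) != "absorbing":
        raise ValueError(f"{absorbing_state!r} is not an absorbing state")
    hazards = {t: nelson_aalen(episodes, t) for t in graph.transitions}
    step_fns = {t: (h.times, h.increments) for t, h in hazards.items()}
    tpm = aalen_johansen(step_fns, graph, t0=0.0)
    # empirical initial-state distribution: state occupied at t = 0
    first = episodes[episodes["tstart"] == 0.0].groupby("id")["from_state"].first()
    if not len(first):
        return pd.DataFrame({"time": [0.0], "probability": [0.0]})
    pi0 = np.zeros(graph.n_states)
    for s, cnt in first.value_counts().items():
        pi0[graph.states.index(s)] = cnt
    pi0 = pi0 / pi0.sum()
    j = graph.states.index(absorbing_state)
    probs = np.einsum("k,tkl->tl", pi0, tpm.matrices)[:, j]
    return pd.DataFrame({"time": tpm.times, "probability": probs})
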