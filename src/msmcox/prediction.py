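"""Individual prediction: transition-probability matrices and
state-occupancy summaries for a covariate profile.

Given a fitted multistate Cox model, the profile-specific cumulative
hazards ``Lambda_kl(t; z) = Lambda_kl0(t) * exp(beta_kl' z_kl)`` feed the
Aalen-Johansen product integral

    P(t0, t) = prod_{t0 < t_j <= t} (I + dLambda(t_j))

taken over the pooled jump times, where the off-diagonal (k, l) entry of
``dLambda(t_j)`` is that transition's hazard increment and each diagonal
entry is minus the row sum.  Each factor is a stochastic matrix, so rows of
``P`` sum to one and Chapman-Kolmogorov holds exactly on the jump grid.
Baseline hazards are step functions (right-continuous); no interpolation
between jumps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxmsm import CoxError, MsmFit
from .state_graph import StateGraph

__all__ = [
    "Profile",
    "TransitionProbabilityMatrix",
    "profile_hazards",
    "aalen_johansen",
    "occupancy",
    "most_likely_state",
]


@dataclass(frozen=True)
class Profile:
    """A new individual: baseline covariate values, starting state, and
    prediction origin ``t0`` (default 0, baseline prediction)."""

    covariates: dict
    start_state: str
    t0: float = 0.0


@dataclass
class TransitionProbabilityMatrix:
    """``P(t0, t)`` on a time grid: ``matrices[i]`` is the R x R stochastic
    matrix for ``times[i]`` with state order ``states``."""

    states: tuple[str, ...]
    times: np.ndarray
    matrices: np.ndarray  # (T, R, R)
    t0: float = 0.0
    provenance: dict = field(default_factory=dict)

    def at(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            raise ValueError(f"time {t} precedes the prediction origin {self.t0}")
        return self.matrices[idx]

    def occupancy_from(self, start_state: str) -> pd.DataFrame:
        i = self.states.index(start_state)
        df = pd.DataFrame(self.matrices[:, i, :], columns=list(self.states))
        df.insert(0, "time", self.times)
        return df


def profile_hazards(fit: MsmFit, profile: Profile) -> dict:
    """Per-transition cumulative-hazard step functions for one profile.

    Returns ``{(k, l): (jump_times, increments)}``; transitions without
    events contribute zero hazard.  Missing profile covariates are rejected
    by name.
    """
    out = {}
    for trans, tf in fit.fits.items():
        if len(tf.beta):
            z = tf.design.profile_vector(profile.covariates)
            mult = float(np.exp(tf.beta @ z))
        else:
            mult = 1.0
        out[trans] = (tf.baseline_times, tf.baseline_increments * mult)
    for trans in fit.unfit:
        out[trans] = (np.array([]), np.array([]))
    return out


def aalen_johansen(
    hazards: dict,
    graph: StateGraph,
    t0: float = 0.0,
    t_grid=None,
) -> TransitionProbabilityMatrix:
    """Product-integral transition-probability matrix from cumulative-hazard
    step functions.

    ``hazards`` maps each transition to ``(jump_times, increments)``.  If a
    jump's total outgoing mass for some state exceeds 1 (diagonal of the
    factor would go negative), the row's off-diagonal entries are rescaled
    to sum to 1 with diagonal 0, and a warning identifies the time and
    state — this preserves row-stochasticity rather than propagating
    negative probabilities.
    """
    R = graph.n_states
    idx = {s: i for i, s in enumerate(graph.states)}
    all_times = np.unique(
        np.concatenate(
            [np.asarray(ts, dtype=float)[np.asarray(ts, dtype=float) > t0]
             for ts, _ in hazards.values()] or [np.array([])]
        )
    )
    grid = np.asarray(t_grid, dtype=float) if t_grid is not None else None
    if grid is not None and np.any(grid < t0):
        raise ValueError("t_grid must lie in [t0, infinity)")
    out_times = np.unique(np.concatenate([[t0], all_times, grid])) if grid is not None \
        else np.concatenate([[t0], all_times])

    # per-transition increments aligned to pooled jump times
    inc = np.zeros((len(all_times), R, R))
    for (k, l), (ts, dh) in hazards.items():
        ts = np.asarray(ts, dtype=float)
        dh = np.asarray(dh, dtype=float)
        keep = ts > t0
        pos = np.searchsorted(all_times, ts[keep])
        inc[pos, idx[k], idx[l]] += dh[keep]

    P = np.eye(R)
    mats = np.empty((len(out_times), R, R))
    j = 0
    for i, t in enumerate(out_times):
        while j < len(all_times) and all_times[j] <= t:
            dL = inc[j].copy()
            rowsum = dL.sum(axis=1)
            over = np.where(rowsum > 1.0)[0]
            for r in over:
                warnings.warn(
                    f"jump mass {rowsum[r]:.4g} > 1 for state "
                    f"{graph.states[r]!r} at t={all_times[j]:.6g}; row rescaled"
                )
                dL[r] /= rowsum[r]
                rowsum[r] = 1.0
            factor = np.eye(R) + dL - np.diag(rowsum)
            P = P @ factor
            j += 1
        mats[i] = P
    return TransitionProbabilityMatrix(
        states=graph.states, times=out_times, matrices=mats, t0=t0
    )


@dataclass
class OccupancyResult:
    """Per-state occupancy probabilities for one profile."""

    profile: Profile
    horizon: float
    at_horizon: pd.Series          # probability per state at the horizon
    curves: pd.DataFrame           # time x state occupancy curves
    extrapolated: bool             # horizon beyond the last hazard jump

    @property
    def most_likely_state(self) -> str:
        return most_likely_state(self.at_horizon)


def occupancy(fit: MsmFit, profile: Profile, horizon: float) -> OccupancyResult:
    """Occupancy probabilities of a profile at a horizon plus full curves.

    The start-state row of ``P(t0, tau)``; beyond the last observed jump
    the probabilities are held constant (flagged ``extrapolated``).
    """
    if horizon <= profile.t0:
        raise ValueError("horizon must exceed the prediction origin t0")
    if profile.start_state not in fit.graph.states:
        raise CoxError(f"unknown start state {profile.start_state!r}")
    hz = profile_hazards(fit, profile)
    tpm = aalen_johansen(hz, fit.graph, t0=profile.t0, t_grid=[horizon])
    curves = tpm.occupancy_from(profile.start_state)
    row = tpm.at(horizon)[fit.graph.states.index(profile.start_state)]
    last_jump = max(
        (ts[-1] for ts, _ in hz.values() if len(ts)), default=profile.t0
    )
    if horizon > last_jump:
        warnings.warn(
            f"horizon {horizon} exceeds the last observed event time "
            f"{last_jump}; probabilities held constant beyond it"
        )
    return OccupancyResult(
        profile=profile, horizon=horizon,
        at_horizon=pd.Series(row, index=list(fit.graph.states)),
        curves=curves, extrapolated=bool(horizon > last_jump),
    )


def most_likely_state(occupancy_at_tau: pd.Series) -> str:
    """State with the highest occupancy probability; exact ties broken by
    the smallest state index (the declared deterministic rule)."""
    vals = occupancy_at_tau.to_numpy(dtype=float)
    return str(occupancy_at_tau.index[int(np.argmax(vals))])
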