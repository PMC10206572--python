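"""Subject-level event-history data: wide format, counting-process expansion,
and pre-model descriptive summaries.

Wide format contract (delimited text, header row, UTF-8, missing = empty):
one row per subject with columns

    ``id``, ``start_state``, then ``<state>_time`` and ``<state>_status`` for
    every non-initial state, then baseline covariates.

``<state>_status`` is 1 if the subject entered that state at
``<state>_time`` (days from the time origin) and 0 otherwise, in which case
``<state>_time`` records the time up to which entry could have been
observed (the censoring time for transitions into that state).

The counting-process *episode* expansion turns each visited non-absorbing
state into one row per outgoing (competing) transition, all sharing the
entry/exit interval, with status 1 only on the transition actually taken.
All model fitting operates on this long format; a single forward clock
(time since study entry) is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .state_graph import StateGraph

__all__ = [
    "DataError",
    "SubjectPath",
    "wide_columns",
    "read_subjects",
    "write_subjects",
    "subject_paths",
    "validate_subjects",
    "expand_to_episodes",
    "transition_counts",
    "epv_check",
    "length_of_stay",
    "filter_subjects",
    "covariate_columns",
]

EPISODE_COLUMNS = ["id", "from_state", "to_state", "trans", "tstart", "tstop", "status"]


class DataError(ValueError):
    """Raised when subject data violate the wide-format contract."""


@dataclass
class SubjectPath:
    """Reconstructed trajectory of one subject.

    ``states`` and ``times`` are parallel: ``states[j]`` entered at
    ``times[j]`` (``times[0] == 0`` for the starting state).  ``end_time``
    is the entry time of the final state if it is absorbing, otherwise the
    censoring time in that state.
    """

    id: object
    states: list[str]
    times: list[float]
    end_time: float
    censored: bool

    def state_at(self, t: float) -> str | None:
        """State occupied at time ``t``; ``None`` if censored before ``t``
        in a non-absorbing state."""
        if self.censored and t > self.end_time:
            return None
        idx = int(np.searchsorted(np.asarray(self.times), t, side="right")) - 1
        return self.states[idx]


def non_initial_states(graph: StateGraph) -> list[str]:
    return [s for s in graph.states if graph.roles[s] != "initial"]


def wide_columns(graph: StateGraph) -> list[str]:
    cols = ["id", "start_state"]
    for s in non_initial_states(graph):
        cols += [f"{s}_time", f"{s}_status"]
    return cols


def covariate_columns(subjects: pd.DataFrame, graph: StateGraph) -> list[str]:
    structural = set(wide_columns(graph))
    return [c for c in subjects.columns if c not in structural]


def read_subjects(path, graph: StateGraph) -> pd.DataFrame:
    """Read and validate a wide-format CSV."""
    df = pd.read_csv(path)
    validate_subjects(df, graph)
    return df


def write_subjects(subjects: pd.DataFrame, path, graph: StateGraph | None = None) -> None:
    subjects.to_csv(path, index=False)


def _subject_path(row: pd.Series, graph: StateGraph) -> SubjectPath:
    sid = row["id"]
    start = row["start_state"]
    if start not in graph.states:
        raise DataError(f"subject {sid}: unknown start_state {start!r}")
    if graph.roles[start] == "absorbing":
        raise DataError(f"subject {sid}: starts in absorbing state {start!r}")
    entered: list[tuple[float, str]] = []
    for s in non_initial_states(graph):
        st = row[f"{s}_status"]
        if st not in (0, 1):
            raise DataError(f"subject {sid}: {s}_status must be 0 or 1, got {st!r}")
        t = float(row[f"{s}_time"])
        if not np.isfinite(t) or t < 0:
            raise DataError(f"subject {sid}: {s}_time must be finite and >= 0")
        if st == 1:
            entered.append((t, s))
    entered.sort()
    states = [start] + [s for _, s in entered]
    times = [0.0] + [t for t, _ in entered]
    for j in range(1, len(times)):
        if times[j] <= times[j - 1]:
            raise DataError(
                f"subject {sid}: entry times must strictly increase along the "
                f"path (state {states[j]!r} entered at {times[j]} after "
                f"{states[j - 1]!r} at {times[j - 1]}; zero-length stays are "
                "not supported)"
            )
        k, l = states[j - 1], states[j]
        if (k, l) not in graph.transitions:
            raise DataError(
                f"subject {sid}: step {k} -> {l} is not a transition of the graph"
            )
    last = states[-1]
    if graph.roles[last] == "absorbing":
        return SubjectPath(sid, states, times, end_time=times[-1], censored=False)
    succ = graph.successors(last)
    cens_times = [float(row[f"{s}_time"]) for s in succ]
    cens = min(cens_times)
    if cens <= times[-1]:
        raise DataError(
            f"subject {sid}: censoring time {cens} in state {last!r} does not "
            f"exceed its entry time {times[-1]}"
        )
    return SubjectPath(sid, states, times, end_time=cens, censored=True)


def subject_paths(subjects: pd.DataFrame, graph: StateGraph) -> list[SubjectPath]:
    missing = [c for c in wide_columns(graph) if c not in subjects.columns]
    if missing:
        raise DataError(f"wide table is missing columns {missing}")
    if subjects["id"].duplicated().any():
        dupes = subjects.loc[subjects["id"].duplicated(), "id"].tolist()
        raise DataError(f"duplicate subject ids: {dupes[:5]}")
    return [_subject_path(row, graph) for _, row in subjects.iterrows()]


def validate_subjects(subjects: pd.DataFrame, graph: StateGraph) -> None:
    subject_paths(subjects, graph)


def expand_to_episodes(subjects: pd.DataFrame, graph: StateGraph) -> pd.DataFrame:
    """Expand wide subject data to counting-process long format.

    One row per visited non-absorbing state per outgoing transition, with
    shared (tstart, tstop) per state visit and status 1 only on the
    transition taken.  Baseline covariates are carried onto every row.
    """
    paths = subject_paths(subjects, graph)
    covs = covariate_columns(subjects, graph)
    cov_values = subjects.set_index("id")[covs] if covs else None
    rows = []
    for p in paths:
        for j, k in enumerate(p.states):
            if graph.roles[k] == "absorbing":
                continue
            tstart = p.times[j]
            taken = p.states[j + 1] if j + 1 < len(p.states) else None
            tstop = p.times[j + 1] if taken is not None else p.end_time
            for l in graph.successors(k):
                rows.append(
                    (p.id, k, l, graph.transition_index(k, l), tstart, tstop,
                     int(l == taken))
                )
    episodes = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    if cov_values is not None and len(episodes):
        episodes = episodes.join(cov_values, on="id")
    elif cov_values is not None:
        for c in covs:
            episodes[c] = pd.Series(dtype=cov_values[c].dtype)
    return episodes


def transition_counts(episodes: pd.DataFrame) -> pd.DataFrame:
    """Events and at-risk subject counts per transition.

    Because the graph is acyclic no subject can traverse a transition twice,
    so the number of events equals the number of transitioning subjects.
    """
    if not len(episodes):
        return pd.DataFrame(columns=["from_state", "to_state", "events", "at_risk"])
    g = episodes.groupby(["from_state", "to_state"], sort=False)
    out = g.agg(events=("status", "sum"), at_risk=("id", "nunique")).reset_index()
    return out


def epv_check(
    counts: pd.DataFrame,
    covariate_assignment: dict,
    n_coefs: dict | None = None,
    min_epv: int = 5,
) -> list[str]:
    """Events-per-variable screen: flag transitions with fewer than
    ``min_epv`` events per estimated coefficient.

    ``covariate_assignment`` maps transition ``(k, l)`` to its covariate
    list; ``n_coefs`` optionally maps covariate name to its number of
    estimated coefficients (non-reference levels for a factor; default 1).
    Fitting is never blocked, only flagged.
    """
    n_coefs = n_coefs or {}
    events = {(r.from_state, r.to_state): r.events for r in counts.itertuples()}
    out = []
    for trans, covs in covariate_assignment.items():
        p = sum(int(n_coefs.get(c, 1)) for c in covs)
        if p == 0:
            continue
        ev = int(events.get(tuple(trans), 0))
        if ev < min_epv * p:
            k, l = trans
            out.append(
                f"transition {k} -> {l}: {ev} events for {p} coefficient(s); "
                f"at least {min_epv * p} recommended ({min_epv} events per coefficient)"
            )
    return out


def length_of_stay(
    subjects: pd.DataFrame, graph: StateGraph, uncensored_only: bool = True
) -> pd.DataFrame:
    """Five-number length-of-stay summary per initial/transient state.

    Outliers are stays beyond 1.5 times the interquartile range from the
    quartiles (standard box-plot whisker rule).  With ``uncensored_only``
    (the default, matching descriptive use on fully observed data) stays
    ending in censoring are excluded.
    """
    paths = subject_paths(subjects, graph)
    stays: dict[str, list[float]] = {
        s: [] for s in graph.states if graph.roles[s] != "absorbing"
    }
    for p in paths:
        for j, k in enumerate(p.states):
            if graph.roles[k] == "absorbing":
                continue
            exit_t = p.times[j + 1] if j + 1 < len(p.states) else p.end_time
            is_censored_stay = (j + 1 == len(p.states)) and p.censored
            if uncensored_only and is_censored_stay:
                continue
            stays[k].append(exit_t - p.times[j])
    rows = []
    for s, vals in stays.items():
        if not vals:
            rows.append((s, 0, np.nan, np.nan, np.nan, np.nan, np.nan, []))
            continue
        v = np.sort(np.asarray(vals, dtype=float))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo) & (v <= hi)]
        whisk_lo = float(inside.min()) if len(inside) else np.nan
        whisk_hi = float(inside.max()) if len(inside) else np.nan
        outliers = [float(x) for x in v[(v < lo) | (v > hi)]]
        rows.append((s, len(v), med, q1, q3, whisk_lo, whisk_hi, outliers))
    return pd.DataFrame(
        rows,
        columns=["state", "n", "median", "q1", "q3", "whisker_low", "whisker_high", "outliers"],
    )


def filter_subjects(subjects: pd.DataFrame, predicate) -> pd.DataFrame:
    """Row subset by a covariate predicate.

    ``predicate`` is either a pandas query string over covariate columns
    (e.g. ``"wave == 5"``) or a callable mapping the table to a boolean
    mask.  Unknown column names raise :class:`DataError`.
    """
    if callable(predicate):
        mask = predicate(subjects)
        return subjects.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
    try:
        out = subjects.query(predicate)
    except pd.errors.UndefinedVariableError as e:
        raise DataError(f"predicate references an unknown covariate: {e}") from e
    return out.reset_index(drop=True)
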