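"""Synthetic multistate cohorts with known truth.

Subjects move through an acyclic state graph under a clock-forward Markov
process: every transition ``k -> l`` has a baseline intensity (constant or
Weibull in time since study entry) multiplied by ``exp(beta' z)`` for
subject covariates ``z``.  Sojourns are sampled by inverting the total
cumulative exit hazard of the current state; destinations are drawn
proportionally to the instantaneous transition intensities at the event
time.  This is exactly the model class fitted by the Cox machinery, so the
simulator doubles as the truth oracle for parameter-recovery and
prediction-calibration tests.

Censoring is administrative at ``censoring_time`` by default; an optional
independent exponential censoring rate is available for censored-data
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import data_model
from .state_graph import StateGraph, build_graph

__all__ = [
    "TransitionHazard",
    "CovariateSpec",
    "IntensitySpec",
    "simulate_paths",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class TransitionHazard:
    """Baseline intensity of one transition plus log-linear covariate effects.

    ``family`` is ``"constant"`` (parameter ``rate``) or ``"weibull"``
    (``shape`` a, ``scale`` b, cumulative hazard ``(t/b)**a``); ``beta``
    maps covariate name to its log hazard ratio on this transition.
    """

    family: str = "constant"
    rate: float = 1.0
    shape: float = 1.0
    scale: float = 1.0
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("constant", "weibull"):
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.family == "constant" and self.rate <= 0:
            raise ValueError("constant hazard rate must be > 0")
        if self.family == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("weibull shape and scale must be > 0")

    def cumhaz(self, t: float) -> float:
        if self.family == "constant":
            return self.rate * t
        return (t / self.scale) ** self.shape

    def intensity(self, t: float) -> float:
        if self.family == "constant":
            return self.rate
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)


@dataclass(frozen=True)
class CovariateSpec:
    """Baseline covariate generator: ``binary`` (prevalence ``p``) or
    ``normal`` (``mean``, ``sd``)."""

    kind: str
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("binary", "normal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 <= self.p <= 1.0:
            raise ValueError("binary prevalence must be in [0, 1]")
        if self.kind == "normal" and self.sd <= 0:
            raise ValueError("normal sd must be > 0")

    def draw(self, rng: np.random.Generator):
        if self.kind == "binary":
            return int(rng.random() < self.p)
        return float(rng.normal(self.mean, self.sd))


@dataclass(frozen=True)
class IntensitySpec:
    """Full specification of the generating process for one cohort."""

    hazards: dict  # (k, l) -> TransitionHazard
    covariates: dict = field(default_factory=dict)  # name -> CovariateSpec
    censoring_time: float = np.inf
    censoring_rate: float | None = None
    initial_dist: dict = field(default_factory=dict)  # state -> probability

    def validate(self, graph: StateGraph) -> None:
        for t in graph.transitions:
            if t not in self.hazards:
                raise ValueError(
                    f"no hazard specified for transition {t[0]} -> {t[1]}; a "
                    "state with outgoing transitions but zero hazard would "
                    "never be left"
                )
        for (k, l) in self.hazards:
            if (k, l) not in graph.transitions:
                raise ValueError(f"hazard given for unknown transition {k} -> {l}")
        if not self.initial_dist:
            raise ValueError("initial_dist is empty")
        tot = sum(self.initial_dist.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"initial distribution sums to {tot}, not 1")
        for s, p in self.initial_dist.items():
            if graph.roles.get(s) == "absorbing":
                raise ValueError(f"initial state {s!r} is absorbing")
            if not 0.0 <= p <= 1.0:
                raise ValueError("initial probabilities must be in [0, 1]")


def _draw_sojourn(graph, spec, state, t, multipliers, rng) -> tuple[float, str]:
    """Next event time and destination from `state` occupied at time t."""
    succ = graph.successors(state)
    hz = [spec.hazards[(state, l)] for l in succ]
    m = [multipliers[(state, l)] for l in succ]
    e = rng.exponential()
    if all(h.family == "constant" for h in hz):
        total = sum(h.rate * mi for h, mi in zip(hz, m))
        u = t + e / total
    else:
        def g(u):
            return sum((h.cumhaz(u) - h.cumhaz(t)) * mi for h, mi in zip(hz, m)) - e

        hi = max(t, 1.0)
        while g(hi) < 0:
            hi = 2.0 * hi + 1.0
            if hi > 1e12:
                raise RuntimeError("sojourn inversion failed to bracket")
        u = brentq(g, t, hi, xtol=1e-10)
    lam = np.array([h.intensity(u) * mi for h, mi in zip(hz, m)], dtype=float)
    dest = succ[rng.choice(len(succ), p=lam / lam.sum())]
    return u, dest


def simulate_paths(
    graph: StateGraph, spec: IntensitySpec, n: int, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate ``n`` subjects; return the wide-format table plus the hidden
    truth record (full paths, censoring, transition tally).

    Identical ``(seed, n, spec)`` produce bit-identical output.
    """
    spec.validate(graph)
    rng = np.random.default_rng(seed)
    init_states = sorted(spec.initial_dist, key=graph.states.index)
    init_p = np.array([spec.initial_dist[s] for s in init_states])
    cov_names = list(spec.covariates)
    non_init = data_model.non_initial_states(graph)

    records, truth_paths = [], []
    tally: dict[tuple[str, str], int] = {t: 0 for t in graph.transitions}
    for i in range(n):
        z = {c: spec.covariates[c].draw(rng) for c in cov_names}
        mult = {
            (k, l): float(np.exp(sum(h.beta.get(c, 0.0) * z[c] for c in h.beta)))
            for (k, l), h in spec.hazards.items()
        }
        cens = spec.censoring_time
        if spec.censoring_rate is not None:
            cens = min(cens, rng.exponential(1.0 / spec.censoring_rate))
        state = init_states[rng.choice(len(init_states), p=init_p)]
        t = 0.0
        path = [(state, 0.0)]
        censored = False
        while graph.roles[state] != "absorbing":
            u, dest = _draw_sojourn(graph, spec, state, t, mult, rng)
            if u >= cens:
                censored = True
                break
            tally[(state, dest)] += 1
            state, t = dest, u
            path.append((state, t))
        end_time = cens if censored else t
        entered = dict((s, tt) for s, tt in path[1:])
        row = {"id": i + 1, "start_state": path[0][0]}
        for s in non_init:
            if s in entered:
                row[f"{s}_time"], row[f"{s}_status"] = entered[s], 1
            else:
                row[f"{s}_time"], row[f"{s}_status"] = end_time, 0
        row.update(z)
        records.append(row)
        truth_paths.append(
            {"id": i + 1, "path": path, "censored": censored, "end_time": end_time,
             "covariates": z}
        )
    subjects = pd.DataFrame(records)
    truth = {
        "paths": truth_paths,
        "transition_tally": tally,
        "seed": seed,
        "n": n,
    }
    return subjects, truth


# ---------------------------------------------------------------------------
# Named fixtures: small, versioned datasets with stored expectations.
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("toy-3-subjects", "illness-death-500", "seven-state-hospital")

ILLNESS_DEATH_RATES = {"h->i": 0.1, "h->d": 0.05, "i->d": 0.2}


def illness_death_graph() -> StateGraph:
    return build_graph(
        ["healthy", "ill", "dead"],
        [("healthy", "ill"), ("healthy", "dead"), ("ill", "dead")],
    )


def seven_state_graph() -> StateGraph:
    """A hospital-course structure with 2 initial, 3 transient and 2
    absorbing states and 14 transitions (acute respiratory cohort shape):
    admission without (`nopneum`) or with (`pneum`) severe pneumonia,
    ventilation states `nimv`/`imv`, `reco`very, and the absorbing
    `dcharg`/`death`."""
    states = ["nopneum", "pneum", "nimv", "imv", "reco", "dcharg", "death"]
    transitions = [
        ("nopneum", "reco"), ("nopneum", "dcharg"), ("nopneum", "death"),
        ("pneum", "nimv"), ("pneum", "imv"), ("pneum", "reco"), ("pneum", "death"),
        ("nimv", "imv"), ("nimv", "reco"), ("nimv", "death"),
        ("imv", "reco"), ("imv", "death"),
        ("reco", "dcharg"), ("reco", "death"),
    ]
    return build_graph(states, transitions)


def _toy_fixture() -> dict:
    graph = illness_death_graph()
    subjects = pd.DataFrame(
        {
            "id": [1, 2, 3],
            "start_state": ["healthy", "healthy", "healthy"],
            "ill_time": [3.0, 5.0, 4.0],
            "ill_status": [1, 0, 0],
            "dead_time": [10.0, 5.0, 4.0],
            "dead_status": [1, 0, 1],
        }
    )
    # hand-derived counting-process expansion
    expected_episodes = pd.DataFrame(
        [
            (1, "healthy", "ill", 1, 0.0, 3.0, 1),
            (1, "healthy", "dead", 2, 0.0, 3.0, 0),
            (1, "ill", "dead", 3, 3.0, 10.0, 1),
            (2, "healthy", "ill", 1, 0.0, 5.0, 0),
            (2, "healthy", "dead", 2, 0.0, 5.0, 0),
            (3, "healthy", "ill", 1, 0.0, 4.0, 0),
            (3, "healthy", "dead", 2, 0.0, 4.0, 1),
        ],
        columns=data_model.EPISODE_COLUMNS,
    )
    expected_counts = {("healthy", "ill"): 1, ("healthy", "dead"): 1, ("ill", "dead"): 1}
    # Nelson-Aalen by hand: h->i jumps at t=3 with Y=3; h->d at t=4 with Y=1
    # (subjects 1 left at 3, 2 at risk until 5 -> at t=4 risk={2,3}, so Y=2);
    # i->d at t=10 with Y=1.
    expected_nelson_aalen = {
        ("healthy", "ill"): [(3.0, 1.0 / 3.0)],
        ("healthy", "dead"): [(4.0, 1.0 / 2.0)],
        ("ill", "dead"): [(10.0, 1.0)],
    }
    return {
        "name": "toy-3-subjects",
        "graph": graph,
        "subjects": subjects,
        "spec": None,
        "seed": None,
        "expected": {
            "episodes": expected_episodes,
            "counts": expected_counts,
            "nelson_aalen": expected_nelson_aalen,
        },
    }


def illness_death_spec(
    beta_treat: float = float(np.log(2.0)), censoring_time: float = 30.0
) -> IntensitySpec:
    """Constant-intensity illness-death process with one binary covariate
    acting on the healthy -> ill transition."""
    return IntensitySpec(
        hazards={
            ("healthy", "ill"): TransitionHazard(
                rate=ILLNESS_DEATH_RATES["h->i"], beta={"treat": beta_treat}
            ),
            ("healthy", "dead"): TransitionHazard(rate=ILLNESS_DEATH_RATES["h->d"]),
            ("ill", "dead"): TransitionHazard(rate=ILLNESS_DEATH_RATES["i->d"]),
        },
        covariates={"treat": CovariateSpec("binary", p=0.5)},
        censoring_time=censoring_time,
        initial_dist={"healthy": 1.0},
    )


def seven_state_spec() -> IntensitySpec:
    """Generating process for the seven-state cohort: daily exit rates sized
    for a 30-day hospital course (median invasive-ventilation stay of about
    two weeks, overall in-hospital mortality of a few percent), an age
    effect on the transitions into death and an immunosuppression effect on
    the invasive-ventilation -> death transition."""
    beta_age = 0.02  # per year of age, on death transitions
    beta_immune = float(np.log(3.32))
    hz = {
        ("nopneum", "reco"): TransitionHazard(rate=0.08),
        ("nopneum", "dcharg"): TransitionHazard(rate=0.15),
        ("nopneum", "death"): TransitionHazard(rate=0.001, beta={"age_c": beta_age}),
        ("pneum", "nimv"): TransitionHazard(rate=0.06),
        ("pneum", "imv"): TransitionHazard(rate=0.04),
        ("pneum", "reco"): TransitionHazard(rate=0.10),
        ("pneum", "death"): TransitionHazard(rate=0.002, beta={"age_c": beta_age}),
        ("nimv", "imv"): TransitionHazard(rate=0.05),
        ("nimv", "reco"): TransitionHazard(rate=0.10),
        ("nimv", "death"): TransitionHazard(rate=0.003, beta={"age_c": beta_age}),
        ("imv", "reco"): TransitionHazard(rate=0.035),
        ("imv", "death"): TransitionHazard(
            rate=0.012, beta={"age_c": beta_age, "immune": beta_immune}
        ),
        ("reco", "dcharg"): TransitionHazard(rate=0.25),
        ("reco", "death"): TransitionHazard(rate=0.001, beta={"age_c": beta_age}),
    }
    return IntensitySpec(
        hazards=hz,
        covariates={
            "age_c": CovariateSpec("normal", mean=0.0, sd=12.0),  # age centred at 65
            "sex": CovariateSpec("binary", p=0.5),
            "immune": CovariateSpec("binary", p=0.15),
        },
        censoring_time=30.0,
        initial_dist={"nopneum": 0.8, "pneum": 0.2},
    )


def make_fixture(name: str) -> dict:
    """Return a named, versioned fixture bundle.

    Keys: ``graph``, ``subjects`` (wide table), ``spec`` (generator truth,
    ``None`` for the hand-built toy), ``truth`` (simulation record where
    applicable), ``seed`` and ``expected`` (stored expectations).
    Regenerating a fixture from its recorded seed is bit-identical.
    """
    if name == "toy-3-subjects":
        return _toy_fixture()
    if name == "illness-death-500":
        graph = illness_death_graph()
        spec = illness_death_spec()
        seed = 20230524
        subjects, truth = simulate_paths(graph, spec, n=500, seed=seed)
        return {
            "name": name, "graph": graph, "subjects": subjects, "spec": spec,
            "truth": truth, "seed": seed,
            "expected": {"beta": {("healthy", "ill"): {"treat": float(np.log(2.0))}},
                         "counts": truth["transition_tally"]},
        }
    if name == "seven-state-hospital":
        graph = seven_state_graph()
        spec = seven_state_spec()
        seed = 690
        subjects, truth = simulate_paths(graph, spec, n=690, seed=seed)
        return {
            "name": name, "graph": graph, "subjects": subjects, "spec": spec,
            "truth": truth, "seed": seed,
            "expected": {"n_initial": 2, "n_transient": 3, "n_absorbing": 2,
                         "counts": truth["transition_tally"]},
        }
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
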