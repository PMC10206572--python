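"""Predictive-performance assessment and model comparison.

The **logarithmic score** for n individuals evaluated at horizon ``t1`` is
the mean negative log probability the model assigned to each individual's
realized state,

    LS = -(1/n) * sum_i log P_i{X_i(t1) = x_i(t1)},

nonnegative, 0 for perfect forecasts, and lower for better models; by
itself it has no absolute interpretation, so it is used to compare models
on the same data.  The **confusion matrix** cross-tabulates predicted
(rows: each subject's most-likely state at ``t1``) against realized
(columns) states; per-state accuracy is the diagonal over the column
total.

Subjects censored before ``t1`` in a non-absorbing state have no realized
state and are excluded with a count — never silently scored.  Predicted
probabilities are floored at 1e-12 before the log (the score is otherwise
unbounded); flooring is flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data_model
from .coxmsm import MsmFit
from .prediction import Profile, most_likely_state, occupancy

__all__ = ["PROB_FLOOR", "log_score", "confusion_matrix", "ScoreReport", "ModelRegistry"]

PROB_FLOOR = 1e-12


@dataclass
class LogScoreResult:
    value: float
    n: int
    n_floored: int

    @property
    def floored(self) -> bool:
        return self.n_floored > 0


def log_score(predicted_probs, observed_states, states=None) -> LogScoreResult:
    """Logarithmic score from per-subject occupancy vectors.

    ``predicted_probs``: (n, R) array or DataFrame of per-state
    probabilities (each row summing to 1); ``observed_states``: realized
    state label (or column index) per subject.
    """
    if isinstance(predicted_probs, pd.DataFrame):
        states = list(predicted_probs.columns)
        P = predicted_probs.to_numpy(dtype=float)
    else:
        P = np.asarray(predicted_probs, dtype=float)
    n = P.shape[0]
    if n == 0:
        raise ValueError("no subjects to score")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability vector must sum to 1")
    if states is not None:
        cols = np.array([states.index(s) for s in observed_states])
    else:
        cols = np.asarray(observed_states, dtype=int)
    picked = P[np.arange(n), cols]
    n_floored = int(np.sum(picked < PROB_FLOOR))
    return LogScoreResult(
        value=float(-np.mean(np.log(np.maximum(picked, PROB_FLOOR)))),
        n=n, n_floored=n_floored,
    )


@dataclass
class ScoreReport:
    horizon: float
    n_evaluated: int
    n_excluded: int
    log_score: float
    n_floored: int
    confusion: pd.DataFrame          # rows = predicted, columns = real
    per_state_accuracy: pd.Series    # diagonal / column total
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "horizon": self.horizon,
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "log_score": self.log_score,
            "n_floored": self.n_floored,
            "states": list(self.confusion.columns),
            "confusion": self.confusion.to_numpy().tolist(),
            "per_state_accuracy": {
                k: (None if pd.isna(v) else v)
                for k, v in self.per_state_accuracy.items()
            },
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreReport":
        states = d["states"]
        conf = pd.DataFrame(d["confusion"], index=states, columns=states)
        acc = pd.Series(
            {k: (np.nan if v is None else v) for k, v in d["per_state_accuracy"].items()}
        )
        return cls(
            horizon=d["horizon"], n_evaluated=d["n_evaluated"],
            n_excluded=d["n_excluded"], log_score=d["log_score"],
            n_floored=d["n_floored"], confusion=conf,
            per_state_accuracy=acc, note=d.get("note", ""),
        )


def confusion_matrix(fit: MsmFit, subjects: pd.DataFrame, t1: float) -> ScoreReport:
    """Confusion matrix, per-state accuracy and log score at horizon t1.

    Each subject's occupancy is predicted from their baseline profile and
    start state (t0 = 0); the realized state is the state occupied at t1.
    Occupancy vectors are cached per distinct profile, so cohorts with few
    covariate patterns evaluate quickly.
    """
    graph = fit.graph
    paths = data_model.subject_paths(subjects, graph)
    covs = sorted({c for cl in fit.covariate_assignment.values() for c in cl})
    states = list(graph.states)
    cache: dict = {}
    pred_rows, realized, probs = [], [], []
    n_excluded = 0
    sub_idx = subjects.set_index("id")
    for p in paths:
        real = p.state_at(t1)
        if real is None:
            n_excluded += 1
            continue
        row = sub_idx.loc[p.id]
        key = (p.states[0],) + tuple(row[c] for c in covs)
        if key not in cache:
            prof = Profile(
                covariates={c: row[c] for c in covs}, start_state=p.states[0]
            )
            occ = occupancy(fit, prof, horizon=t1)
            cache[key] = occ.at_horizon
        vec = cache[key]
        probs.append(vec.to_numpy())
        pred_rows.append(most_likely_state(vec))
        realized.append(real)
    if not pred_rows:
        return ScoreReport(
            horizon=t1, n_evaluated=0, n_excluded=n_excluded,
            log_score=float("nan"), n_floored=0,
            confusion=pd.DataFrame(0, index=states, columns=states),
            per_state_accuracy=pd.Series(np.nan, index=states),
            note="no evaluable subjects: all censored before the horizon",
        )
    conf = pd.DataFrame(0, index=states, columns=states)
    for pr, re in zip(pred_rows, realized):
        conf.loc[pr, re] += 1
    col_tot = conf.sum(axis=0)
    acc = pd.Series(
        [conf.loc[s, s] / col_tot[s] if col_tot[s] > 0 else np.nan for s in states],
        index=states,
    )
    ls = log_score(np.vstack(probs), realized, states=states)
    return ScoreReport(
        horizon=t1, n_evaluated=len(pred_rows), n_excluded=n_excluded,
        log_score=ls.value, n_floored=ls.n_floored,
        confusion=conf, per_state_accuracy=acc,
    )


class ModelRegistry:
    """Append-only registry of fitted models for comparison.

    Each entry is keyed by a user label and stores the totals needed to
    rank models (log-likelihood, AIC, log score when evaluated).  Save and
    load round-trip every stored number exactly (JSON shortest-repr floats).
    """

    def __init__(self):
        self._entries: dict[str, dict] = {}

    def add(
        self,
        label: str,
        fit: MsmFit | None = None,
        report: ScoreReport | None = None,
        **extra,
    ) -> None:
        if label in self._entries:
            raise ValueError(f"duplicate model label {label!r}")
        entry = dict(extra)
        if fit is not None:
            entry["total_loglik"] = fit.total_loglik
            entry["total_loglik0"] = fit.total_loglik0
            entry["total_AIC"] = fit.total_aic
            entry["n_transitions_fitted"] = len(fit.fits)
        if report is not None:
            entry["log_score"] = report.log_score
            entry["horizon"] = report.horizon
            entry["n_evaluated"] = report.n_evaluated
        self._entries[label] = entry

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self._entries, orient="index")
        df = df[sorted(df.columns)]  # deterministic order, survives save/load
        df.index.name = "label"
        return df.reset_index()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            # insertion order is meaningful (append-only registry)
            json.dump({"entries": self._entries}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelRegistry":
        with open(path) as fh:
            d = json.load(fh)
        reg = cls()
        reg._entries = d["entries"]
        return reg
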