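"""Transition-specific Cox proportional-hazards fitting for Markov
multistate models.

Under the Markov assumption the likelihood factorizes over transitions, so
each transition ``k -> l`` gets its own Cox model

    lambda_kl(t; z) = lambda_kl0(t) * exp(beta_kl' z)

fitted by Newton-Raphson maximization of the partial likelihood on that
transition's counting-process episodes (Breslow tie handling by default,
Efron available).  The accompanying Breslow baseline estimator

    dLambda_kl0(t_j) = dN_kl(t_j) / sum_{i in risk set} exp(beta' z_i)

reduces exactly to the Nelson-Aalen estimator when no covariates are
fitted, an identity the test-suite enforces to machine precision.

Covariates are internally centred at their transition-specific sample means
for numerical stability; reported coefficients, covariance and baseline are
on the original scale (both the score equation and the observed information
are invariant to centring; only the baseline needs the ``exp(-beta'mean)``
back-transformation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .state_graph import StateGraph

__all__ = [
    "CoxError",
    "DesignInfo",
    "TransitionCoxFit",
    "MsmFit",
    "fit_transition_cox",
    "fit_msm",
    "hazard_ratio_table",
    "gof_tests",
    "aic",
]


class CoxError(RuntimeError):
    """Raised when a transition-specific Cox fit is impossible or fails."""


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Maps named covariates (numeric or categorical) to design columns.

    Categorical covariates are reference-coded; the reference is the first
    level in sorted order unless overridden.
    """

    covariates: list[str]
    columns: list[str]
    categorical: dict[str, dict]  # cov -> {"levels": [...], "reference": level}
    column_parent: dict[str, str]

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, covariates: list[str], reference: dict | None = None
    ) -> "DesignInfo":
        reference = reference or {}
        columns, categorical, parent = [], {}, {}
        for c in covariates:
            if c not in df.columns:
                raise CoxError(f"covariate {c!r} not found in the data")
            col = df[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(col.dropna().unique().tolist())
                ref = reference.get(c, levels[0] if levels else None)
                if ref not in levels:
                    raise CoxError(f"reference level {ref!r} not a level of {c!r}")
                categorical[c] = {"levels": levels, "reference": ref}
                for lev in levels:
                    if lev == ref:
                        continue
                    name = f"{c}[{lev}]"
                    columns.append(name)
                    parent[name] = c
            else:
                columns.append(c)
                parent[c] = c
        return cls(covariates=list(covariates), columns=columns,
                   categorical=categorical, column_parent=parent)

    def build(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.columns:
            c = self.column_parent[name]
            if c in self.categorical:
                lev = name[len(c) + 1 : -1]
                levels = [str(x) for x in self.categorical[c]["levels"]]
                # recover the original-typed level by string match
                orig = self.categorical[c]["levels"][levels.index(lev)]
                cols.append((df[c] == orig).astype(float).to_numpy())
            else:
                cols.append(df[c].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def profile_vector(self, profile: dict) -> np.ndarray:
        out = []
        for name in self.columns:
            c = self.column_parent[name]
            if c not in profile:
                raise CoxError(f"profile is missing covariate {c!r}")
            if c in self.categorical:
                lev = name[len(c) + 1 : -1]
                out.append(1.0 if str(profile[c]) == lev else 0.0)
            else:
                out.append(float(profile[c]))
        return np.asarray(out)

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates, "columns": self.columns,
            "categorical": self.categorical, "column_parent": self.column_parent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignInfo":
        return cls(**d)


# ---------------------------------------------------------------------------
# Partial likelihood machinery
# ---------------------------------------------------------------------------

def _event_groups(tstop, status):
    ev_times = np.unique(tstop[status == 1])
    return ev_times


def _plik_quantities(tstart, tstop, status, X, beta, ties="breslow"):
    """Log partial likelihood, gradient, Hessian and Breslow baseline.

    Counting-process risk sets: at event time u, i is at risk iff
    ``tstart_i < u <= tstop_i``.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    w = np.exp(eta)
    ev_times = _event_groups(tstop, status)
    J = len(ev_times)
    # risk indicator (J, n)
    R = (tstart[None, :] < ev_times[:, None]) & (ev_times[:, None] <= tstop[None, :])
    is_event = status == 1
    ev_idx_by_time = [np.where(is_event & (tstop == u))[0] for u in ev_times]
    d = np.array([len(ix) for ix in ev_idx_by_time], dtype=float)

    WX = w[:, None] * X if p else np.empty((n, 0))
    S0 = R @ w
    S1 = R @ WX if p else np.empty((J, 0))
    if p:
        S2 = np.einsum("jn,ni,nk->jik", R.astype(float), WX, X)
    else:
        S2 = np.empty((J, 0, 0))

    loglik = float(eta[is_event].sum())
    grad = X[is_event].sum(axis=0) if p else np.zeros(0)
    hess = np.zeros((p, p))
    base_inc = np.zeros(J)

    if ties == "breslow":
        loglik -= float(np.sum(d * np.log(S0)))
        base_inc = d / S0
        if p:
            zbar = S1 / S0[:, None]
            grad = grad - (d[:, None] * zbar).sum(axis=0)
            hess = -np.einsum("j,jik->ik", d, S2 / S0[:, None, None]) \
                   + np.einsum("j,ji,jk->ik", d, zbar, zbar)
    elif ties == "efron":
        for j, u in enumerate(ev_times):
            ix = ev_idx_by_time[j]
            dj = len(ix)
            s0t = w[ix].sum()
            s1t = WX[ix].sum(axis=0) if p else np.zeros(0)
            s2t = (WX[ix].T @ X[ix]) if p else np.zeros((0, 0))
            for r in range(dj):
                f = r / dj
                s0 = S0[j] - f * s0t
                loglik -= np.log(s0)
                base_inc[j] += 1.0 / s0
                if p:
                    s1 = S1[j] - f * s1t
                    s2 = S2[j] - f * s2t
                    zb = s1 / s0
                    grad = grad - zb
                    hess = hess - (s2 / s0 - np.outer(zb, zb))
    else:
        raise CoxError(f"unknown tie method {ties!r}")
    return loglik, grad, hess, ev_times, base_inc


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class TransitionCoxFit:
    transition: tuple[str, str]
    design: DesignInfo
    beta: np.ndarray           # original scale
    cov: np.ndarray            # inverse observed information
    loglik: float              # at beta-hat
    loglik0: float             # at beta = 0
    n_events: int
    n_episodes: int
    baseline_times: np.ndarray
    baseline_increments: np.ndarray  # Breslow dLambda_0 on original scale
    ties: str
    n_iter: int
    grad_norm: float
    means: np.ndarray          # centring constants
    score0: np.ndarray = field(default=None)
    info0: np.ndarray = field(default=None)

    @property
    def columns(self) -> list[str]:
        return self.design.columns

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)) if self.cov.size else np.array([])

    def baseline_cumhaz_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.baseline_times, t, side="right")
        cum = np.concatenate([[0.0], np.cumsum(self.baseline_increments)])
        return cum[idx]

    def to_dict(self) -> dict:
        return {
            "transition": list(self.transition),
            "design": self.design.to_dict(),
            "beta": self.beta.tolist(), "cov": self.cov.tolist(),
            "loglik": self.loglik, "loglik0": self.loglik0,
            "n_events": self.n_events, "n_episodes": self.n_episodes,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_increments": self.baseline_increments.tolist(),
            "ties": self.ties, "n_iter": self.n_iter, "grad_norm": self.grad_norm,
            "means": self.means.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionCoxFit":
        p = len(d["beta"])
        return cls(
            transition=tuple(d["transition"]),
            design=DesignInfo.from_dict(d["design"]),
            beta=np.asarray(d["beta"]), cov=np.asarray(d["cov"]).reshape(p, p),
            loglik=d["loglik"], loglik0=d["loglik0"],
            n_events=d["n_events"], n_episodes=d["n_episodes"],
            baseline_times=np.asarray(d["baseline_times"]),
            baseline_increments=np.asarray(d["baseline_increments"]),
            ties=d["ties"], n_iter=d["n_iter"], grad_norm=d["grad_norm"],
            means=np.asarray(d["means"]),
        )


@dataclass
class MsmFit:
    """One Cox fit per transition plus totals; the multistate likelihood
    factorizes, so the total log-likelihood is the sum over transitions."""

    graph: StateGraph
    fits: dict  # (k, l) -> TransitionCoxFit
    covariate_assignment: dict
    unfit: list = field(default_factory=list)  # transitions with zero events
    ties: str = "breslow"

    @property
    def total_loglik(self) -> float:
        return float(sum(f.loglik for f in self.fits.values()))

    @property
    def total_loglik0(self) -> float:
        return float(sum(f.loglik0 for f in self.fits.values()))

    @property
    def total_aic(self) -> float:
        return float(sum(-2.0 * f.loglik + 2.0 * len(f.beta) for f in self.fits.values()))

    def to_dict(self) -> dict:
        return {
            "graph": self.graph.to_dict(),
            "fits": {f"{k}->{l}": f.to_dict() for (k, l), f in self.fits.items()},
            "covariate_assignment": {
                f"{k}->{l}": list(v) for (k, l), v in self.covariate_assignment.items()
            },
            "unfit": [list(t) for t in self.unfit],
            "ties": self.ties,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MsmFit":
        graph = StateGraph.from_dict(d["graph"])
        fits = {
            tuple(key.split("->")): TransitionCoxFit.from_dict(v)
            for key, v in d["fits"].items()
        }
        ca = {tuple(k.split("->")): list(v) for k, v in d["covariate_assignment"].items()}
        return cls(graph=graph, fits=fits, covariate_assignment=ca,
                   unfit=[tuple(t) for t in d["unfit"]], ties=d["ties"])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_rank(Xc: np.ndarray, columns: list[str]) -> None:
    if Xc.shape[1] == 0:
        return
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-10:
        _, _, vt = np.linalg.svd(Xc)
        null = vt[-1]
        bad = [columns[i] for i in np.where(np.abs(null) > 0.1)[0]]
        raise CoxError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_transition_cox(
    episodes: pd.DataFrame,
    transition: tuple[str, str],
    covariates: list[str] | None = None,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 50,
    reference: dict | None = None,
) -> TransitionCoxFit:
    """Maximize the partial likelihood for one transition.

    Newton-Raphson with step-halving on non-increase; convergence when the
    relative log-likelihood change falls below ``tol``.  Raises
    :class:`CoxError` on zero events, rank deficiency, non-convergence or
    monotone likelihood (a covariate perfectly separating events).
    """
    covariates = list(covariates or [])
    k, l = transition
    rows = episodes[(episodes["from_state"] == k) & (episodes["to_state"] == l)]
    if not len(rows):
        raise CoxError(f"no episodes for transition {k} -> {l}")
    design = DesignInfo.from_frame(rows, covariates, reference=reference)
    X_full = design.build(rows)
    keep = ~np.isnan(X_full).any(axis=1) if X_full.size else np.ones(len(rows), bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"transition {k} -> {l}: dropped {n_dropped} episode(s) with "
            "missing covariate values (complete-case)"
        )
        rows = rows.loc[keep]
        X_full = X_full[keep]
    tstart = rows["tstart"].to_numpy(dtype=float)
    tstop = rows["tstop"].to_numpy(dtype=float)
    status = rows["status"].to_numpy(dtype=int)
    n_events = int(status.sum())
    if n_events == 0:
        raise CoxError(f"transition {k} -> {l} has zero events; cannot fit")

    p = X_full.shape[1]
    means = X_full.mean(axis=0) if p else np.zeros(0)
    Xc = X_full - means
    _check_rank(Xc, design.columns)

    beta = np.zeros(p)
    ll0, grad0, hess0, _, _ = _plik_quantities(tstart, tstop, status, Xc, beta, ties)
    ll, grad, hess = ll0, grad0, hess0
    n_iter = 0
    if p:
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as e:
                raise CoxError(f"singular information matrix for {k} -> {l}") from e
            new_beta = beta + step
            new_ll, new_grad, new_hess, _, _ = _plik_quantities(
                tstart, tstop, status, Xc, new_beta, ties
            )
            halvings = 0
            while new_ll < ll and halvings < 30:
                step = step / 2.0
                new_beta = beta + step
                new_ll, new_grad, new_hess, _, _ = _plik_quantities(
                    tstart, tstop, status, Xc, new_beta, ties
                )
                halvings += 1
            converged_now = abs(new_ll - ll) <= tol * (abs(ll) + 1e-12)
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            if np.any(np.abs(beta) > 25):
                raise CoxError(
                    f"monotone partial likelihood for {k} -> {l}: a covariate "
                    "appears to perfectly separate events; consider removing it"
                )
            if converged_now:
                break
        else:
            raise CoxError(
                f"Newton-Raphson did not converge for {k} -> {l} in "
                f"{max_iter} iterations (last beta={beta}, loglik={ll})"
            )
    if p and np.any(np.abs(beta) > 15):
        # a coefficient this size (hazard ratio beyond e^15) with a flat
        # likelihood is the signature of monotone likelihood
        raise CoxError(
            f"monotone partial likelihood for {k} -> {l}: a covariate "
            "appears to perfectly separate events; consider removing it"
        )
    # final quantities at beta-hat (centred scale)
    ll_hat, grad_hat, hess_hat, ev_times, base_inc_c = _plik_quantities(
        tstart, tstop, status, Xc, beta, ties
    )
    cov = np.linalg.inv(-hess_hat) if p else np.zeros((0, 0))
    # back to original scale: beta identical; baseline *= exp(-beta' means)
    base_inc = base_inc_c * float(np.exp(-(beta @ means))) if p else base_inc_c
    return TransitionCoxFit(
        transition=(k, l), design=design, beta=beta, cov=cov,
        loglik=float(ll_hat), loglik0=float(ll0),
        n_events=n_events, n_episodes=len(rows),
        baseline_times=ev_times, baseline_increments=base_inc,
        ties=ties, n_iter=n_iter, grad_norm=float(np.linalg.norm(grad_hat)),
        means=means, score0=grad0, info0=-hess0,
    )


def fit_msm(
    episodes: pd.DataFrame,
    graph: StateGraph,
    covariate_assignment: dict | None = None,
    ties: str = "breslow",
    **kwargs,
) -> MsmFit:
    """Fit one Cox model per transition with its assigned covariate subset.

    Transitions absent from ``covariate_assignment`` are fitted as null
    models; transitions with zero observed events are reported in
    ``unfit`` rather than fitted.  Errors from individual transitions are
    re-raised with the transition label attached.
    """
    ca = {tuple(k): list(v) for k, v in (covariate_assignment or {}).items()}
    for trans, covs in ca.items():
        if trans not in graph.transitions:
            raise CoxError(f"covariate assignment references unknown transition {trans}")
        for c in covs:
            if c not in episodes.columns:
                raise CoxError(f"covariate {c!r} (transition {trans}) not in the data")
    fits, unfit = {}, []
    for trans in graph.transitions:
        sub = episodes[
            (episodes["from_state"] == trans[0]) & (episodes["to_state"] == trans[1])
        ]
        if not len(sub) or sub["status"].sum() == 0:
            unfit.append(trans)
            continue
        fits[trans] = fit_transition_cox(
            episodes, trans, ca.get(trans, []), ties=ties, **kwargs
        )
    return MsmFit(graph=graph, fits=fits, covariate_assignment=ca,
                  unfit=unfit, ties=ties)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def hazard_ratio_table(
    fit: MsmFit, level: float = 0.95, scale: dict | None = None
) -> pd.DataFrame:
    """Coefficient table: one row per covariate column per transition.

    ``scale`` maps a covariate name to a multiplier ``c`` so the hazard
    ratio is reported per ``c``-unit change, ``HR = exp(c * beta)`` with a
    Wald interval ``exp(c*beta +/- z * c * se)``.  The p-value tests
    ``beta = 0`` and is unaffected by rescaling.
    """
    scale = dict(scale or {})
    known = {c for f in fit.fits.values() for c in f.design.covariates}
    for c in scale:
        if c not in known:
            raise CoxError(f"scale map names unknown covariate {c!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for (k, l), f in fit.fits.items():
        for j, col in enumerate(f.columns):
            c = scale.get(f.design.column_parent[col], 1.0)
            b, s = f.beta[j], f.se[j]
            wald = b / s if s > 0 else np.inf
            rows.append({
                "covariate": col, "transition": f"{k} -> {l}",
                "coef": b, "scale": c, "HR": np.exp(c * b),
                "ci_low": np.exp(c * b - z * abs(c) * s),
                "ci_high": np.exp(c * b + z * abs(c) * s),
                "p_value": 2.0 * stats.norm.sf(abs(wald)),
            })
    return pd.DataFrame(
        rows, columns=["covariate", "transition", "coef", "scale", "HR",
                       "ci_low", "ci_high", "p_value"]
    )


def gof_tests(tf: TransitionCoxFit) -> pd.DataFrame:
    """Likelihood-ratio, Wald and score tests of the fitted model against
    the null model for one transition (chi-square with p = #coefficients
    degrees of freedom)."""
    p = len(tf.beta)
    out = pd.DataFrame(columns=["test", "statistic", "df", "p_value"])
    if p == 0:
        out.attrs["note"] = "null model: no goodness-of-fit tests"
        return out
    info = np.linalg.inv(tf.cov)
    lrt = 2.0 * (tf.loglik - tf.loglik0)
    wald = float(tf.beta @ info @ tf.beta)
    if tf.score0 is None or tf.info0 is None:
        raise CoxError("score test requires null-model quantities from fitting")
    score = float(tf.score0 @ np.linalg.solve(tf.info0, tf.score0))
    rows = [("likelihood ratio", lrt), ("wald", wald), ("score", score)]
    return pd.DataFrame(
        [(name, st, p, float(stats.chi2.sf(st, p))) for name, st in rows],
        columns=["test", "statistic", "df", "p_value"],
    )


def aic(fit: MsmFit) -> pd.DataFrame:
    """Per-transition and total AIC = -2 loglik + 2 #coefficients."""
    rows = [
        {"transition": f"{k} -> {l}", "loglik": f.loglik, "n_coef": len(f.beta),
         "AIC": -2.0 * f.loglik + 2.0 * len(f.beta)}
        for (k, l), f in fit.fits.items()
    ]
    df = pd.DataFrame(rows, columns=["transition", "loglik", "n_coef", "AIC"])
    df.attrs["total_AIC"] = fit.total_aic
    return df
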