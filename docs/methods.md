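# Methods

## Model

`msmcox` models an individual moving through a finite set of states
$\mathcal{R} = \{1, \dots, R\}$ in continuous time as a Markov multistate
process $X(t)$: given the present state and time, the future path is
independent of the past trajectory.  The transition structure is a directed
acyclic graph; roles follow from the edge set (initial = in-degree 0,
absorbing = out-degree 0, transient otherwise).  Acyclicity is enforced at
construction — the modelling contract is that no individual traverses the
same transition twice, and requiring a DAG is the structural condition that
guarantees it, makes per-transition event and subject counts coincide, and
makes path simulation and episode expansion terminate by construction.

Each transition $k \to l$ carries a proportional-hazards intensity

$$\lambda_{kl}(t; z) = \lambda_{kl,0}(t)\, \exp(\beta_{kl}^\top z_{kl}),$$

with a transition-specific covariate subset $z_{kl}$ and an unspecified
baseline $\lambda_{kl,0}$.  All hazards run on a single forward clock (time
since study entry), so the fitted class is the clock-forward Markov Cox
model.  Under the Markov assumption the likelihood factorizes over
transitions, so each transition is fitted independently on its own
counting-process episodes and totals (log-likelihood, AIC) are sums.

## Data representation

Input is one row per subject in a wide format: `id`, `start_state`, then
`<state>_time` / `<state>_status` per non-initial state, then baseline
covariates.  Expansion to counting-process form creates, for every visited
non-absorbing state, one episode row per outgoing transition sharing the
entry/exit interval `(t_start, t_stop]`, with status 1 only on the
transition taken; the exit or censoring time of the state censors all its
competing transitions.  Zero-length stays are rejected: they would break
`t_start < t_stop` and the risk sets of the partial likelihood, so users
must merge or jitter pass-through states recorded at identical days.
Subjects with missing values in a covariate used by the selected
transitions are dropped per transition with a logged count (complete-case);
the alternative (imputation) is out of scope.  Categorical covariates are
reference-coded with the first sorted level as the default reference.

## Estimation

**Nelson–Aalen.**  The cumulative intensity of $k \to l$ is estimated by
$\hat\Lambda_{kl}(t) = \sum_{t_j \le t} dN_{kl}(t_j) / Y_k(t_j)$, with tied
events aggregated at the tied time.  Instantaneous-hazard curves smooth
these increments with an Epanechnikov kernel; the default bandwidth is one
eighth of the observed window, and near the boundaries the kernel mass
inside the window is renormalized so the curve still integrates
approximately to the total cumulative hazard.  These choices are
deliberately simple and fully declared; tests pin only the unsmoothed
cumulative quantity and the closed-form kernel value, not the cosmetic
shape of the curve.

**Cox partial likelihood.**  Per transition, Newton–Raphson with
step-halving on non-increase maximizes the Breslow-ties log partial
likelihood (Efron available by option) to a relative tolerance of 1e-9
within 50 iterations.  Covariates are centred at the transition sample
means during optimization — the score and observed information are
invariant to centring, so only the Breslow baseline needs the
$\exp(-\hat\beta^\top \bar z)$ back-transformation to the original scale.
Breslow is the default tie method because it makes the identity *null fit
baseline ≡ Nelson–Aalen* exact to machine precision, which the test-suite
enforces on every fixture.  Defects are reported, not papered over: zero
events, rank-deficient designs (named collinear columns), non-convergence,
and monotone likelihood (any $|\hat\beta_j| > 15$, a hazard ratio beyond
$e^{15}$, flags perfect separation).  Hazard-ratio tables use Wald
intervals on the log scale at a configurable level (default 95%), with an
optional per-covariate rescaling $\mathrm{HR} = \exp(c\hat\beta)$ for
reporting effects per, say, 10 units; p-values are unadjusted Wald tests of
$\beta = 0$.  Goodness of fit per transition offers the likelihood-ratio,
Wald and score chi-square statistics against the null model.

## Diagnostics

* **Martingale residuals** $r_i = \delta_i - \hat\Lambda_{kl,0}$ over the
  episode's at-risk window times $\exp(\hat\beta^\top z_i)$; they sum to
  zero at $\hat\beta$ with the Breslow baseline, and smoothed trends over
  continuous covariates assess linearity.
* **dfbetas** (influence).  The default is a one-step Newton approximation
  to the leave-one-out estimate: with episode $i$ removed, one Newton step
  from $\hat\beta$ gives
  $\hat\beta - \hat\beta_{(i)} \approx -I_{(i)}(\hat\beta)^{-1}
  U_{(i)}(\hat\beta)$, standardized by the full-fit standard errors.  This
  costs one gradient/Hessian evaluation per episode and is second-order
  accurate in the deletion; we chose it over the cheaper first-order
  score-residual form (kept as `method="score"`) because in small samples
  with a binary covariate the first-order form understates exactly the
  large influences the diagnostic exists to find — in a survey of simulated
  30-episode fits it missed the exact leave-one-out value by up to 1.5
  standardized units.  The exact full-refit method remains available (and
  is the test oracle), guarded by an episode cap since it refits once per
  episode.
* **Scaled Schoenfeld residuals** at each event time,
  $d \cdot \hat V(\hat\beta) \cdot (z_{(j)} - \bar z(t_j))$ with
  exp-weighted risk-set means; they sum to zero per covariate (the score
  equation).  A local-linear smoothed trend with a pointwise ±2·se band and
  a linear-slope test summarize proportional-hazards violations.

Residual curves use a hand-rolled local-linear smoother (tricube
nearest-neighbour weights, default span 0.75) because the contract the
diagnostics report — does the band cover zero — needs a pointwise standard
error, which off-the-shelf lowess does not provide.  A tiny ridge keeps the
local solve well-posed when all neighbours share one covariate value
(binary covariates).  The band is a working band, not a simultaneous one.

## Prediction

Profile-specific cumulative hazards
$\hat\Lambda_{kl}(t; z) = \hat\Lambda_{kl,0}(t) e^{\hat\beta_{kl}^\top z_{kl}}$
enter the Aalen–Johansen product integral
$P(t_0, t) = \prod_{t_0 < t_j \le t}(I + \Delta\hat\Lambda(t_j))$
over the pooled jump times.  Every factor is a stochastic matrix, so rows
sum to one and Chapman–Kolmogorov holds exactly on the jump grid.  If a
profile's total jump mass out of a state exceeds 1 at some time (possible
for extreme covariate values), that row is rescaled to sum to one with a
zero diagonal and a warning naming the time and state — this preserves the
probability contract instead of propagating negative probabilities.
Baselines are right-continuous step functions; beyond the last observed
event the occupancy is held constant and flagged as extrapolated.
Occupancy summaries report the start-state row of $P(0, \tau)$, the most
likely state (exact ties broken by the smallest state index), and
absorbing-state probabilities; predictions condition on the baseline
profile only, and mid-course prediction from a later state simply starts
the product integral at $t_0 > 0$ with the same fitted hazards.  Cohort
rather than single-profile occupancy (mixing over an initial-state
distribution) is used by the cumulative-incidence display.

## Evaluation

The logarithmic score $-\tfrac1n \sum_i \log \hat P_i\{X_i(t_1) =
x_i(t_1)\}$ combines calibration and sharpness; probabilities are floored
at 1e-12 before the log (the score is otherwise unbounded) and flooring is
flagged.  The confusion matrix cross-tabulates most-likely predicted
states (rows) against realized states (columns) at the horizon; per-state
accuracy is the diagonal over the column total.  Subjects censored before
the horizon in a non-absorbing state have no realized state and are
excluded with a reported count — evaluation is in-sample by default, with
the registry storing totals (log-likelihood, AIC, log score) for model
comparison across sessions.

## Synthetic cohorts

The simulator draws paths from the exact model class being fitted:
clock-forward Markov, constant or Weibull baselines, log-linear covariate
effects.  Sojourns invert the total cumulative exit hazard (closed form for
constant rates, bracketed root-finding to 1e-10 for Weibull — keeping the
simulator Markov in calendar time rather than semi-Markov in sojourn time);
destinations are drawn proportionally to the intensities at the event time.
Censoring is administrative at a fixed horizon by default, with an optional
independent exponential rate.  Three named fixtures are bundled:

* `toy-3-subjects` — a hand-built illness–death table whose episode
  expansion and Nelson–Aalen jumps are stored as hand-derived expectations;
* `illness-death-500` — 500 subjects, constant intensities 0.1 / 0.05 /
  0.2 per day, one binary covariate with true hazard ratio 2 on
  healthy → ill, administrative censoring at day 30;
* `seven-state-hospital` — a 690-subject hospital-course cohort
  (2 initial, 3 transient, 2 absorbing states, 14 transitions) with daily
  exit rates sized for a 30-day course: invasive-ventilation exit time with
  a median near two weeks, overall in-hospital mortality of a few percent,
  an age effect on death transitions and a true hazard ratio of 3.32 for
  immunosuppression on invasive ventilation → death.  The sparse
  transitions into death are present deliberately so the
  events-per-variable screen and transition pruning have something to act
  on.

What passing tests on these cohorts shows — and does not.  The simulator
satisfies proportional hazards, Markovianity and independent censoring by
construction, so recovery and calibration results validate the estimation
machinery, not the model's adequacy for any real cohort; real event-history
data bring tied days, non-proportional effects, informative censoring and
measurement error that the generator (except for the deliberate
tie-handling and time-varying-effect test cases) does not emulate.

## Problem sizes and numerical choices

Test and reproduction runs use cohorts of 200–5000 subjects and replicate
counts of 20–1000, sized so each check has clear resolving power for the
property it pins (e.g. CI coverage bounds [0.90, 0.99] at 200 replicates).
Newton tolerance 1e-9 relative, max 50 iterations with step-halving;
sojourn inversion tolerance 1e-10; probability floor 1e-12; row-sum
contract 1e-9.  Exact identities (Breslow/Nelson–Aalen, product-integral /
Kaplan–Meier duality) are asserted at 1e-12, i.e. machine precision
through the pipeline.

## Known limitations

No left truncation, interval censoring or recurrent states; no
time-dependent covariates; no semi-Markov or parametric fits; no variance
bands for predicted probabilities; no joint fits with shared coefficients
across transitions; evaluation offers no formal calibration/sharpness
decomposition beyond the log score.  The events-per-variable screen warns
but never blocks.
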