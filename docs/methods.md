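# Methods

## Model

`flaretaper` fits a joint latent class mixed model to bDMARD treatment
courses that have reached low disease activity (LDA, DAS28 ≤ 3.2) after at
least 24 weeks of treatment. The follow-up clock of every course starts at
its first qualifying LDA visit. Conditional on an unobserved class
`g ∈ {1..G}`:

* the DAS28 follows a polynomial mean trajectory of order `p` in weeks with
  a course-level random intercept and slope, `(b0, b1) ~ N(0, B)` (B
  unstructured 2×2, shared across classes), and residual variance σ²;
* the time to **first** flare has hazard
  `λ_g(t) = κ ρ^κ t^{κ−1} exp(γ1_g t_yr + γ2_g t_yr² + xᵀβ_s + δ·1[dose(t) ≤ 0.5])`.

Assumptions worth making explicit:

* **Conditional independence**: longitudinal and survival outcomes are
  independent given the class (the standard joint-latent-class assumption;
  no shared random effect links the two submodels).
* **Shared Weibull baseline**: class specificity in the hazard enters only
  through the log-linear and log-quadratic time effects `γ1_g, γ2_g`,
  expressed per year and per year² (`t_yr = weeks/52`); a per-class
  baseline would not be identifiable at the cohort sizes targeted here.
* **Intercept-only class membership**: no covariates enter the class
  probabilities; all covariate effects sit in the survival submodel.
* **First-flare likelihood**: recurrent flares are not modelled in the
  likelihood; courses are right-censored at the last visit. Repeated
  flares only matter to the tapering simulator, where the at-risk clock
  restarts at the most recent flare (renewal assumption) while the full
  DAS28 history continues to feed the class posterior.
* **Courses as sampling units**: patients contributing several courses are
  treated as independent in the likelihood, but cross-validation folds are
  split by patient (stratified by whether the patient ever flared) so no
  patient informs both training and test.

The cumulative hazard integrates the hazard with 15-node Gauss–Legendre
quadrature within each constant-dose segment (the integrand is smooth per
segment; dose changes only at visits). Landmark risk at time `s` over
horizon `h` (default 13 weeks = "3 months") is
`Σ_g w_g(s)·(1 − exp(−[Λ_g(s+h) − Λ_g(s)]))`, with the class posterior
`w_g(s)` combining prior, the marginal density of the DAS28 history up to
`s` (random effects integrated analytically through the rank-2 Woodbury
form), and flare-free survival to `s`. The future dose path over the
horizon defaults to the course's recorded path (on a protocolised course,
the planned next step), with the last dose carried forward.

## Estimation

Maximum likelihood on transformed parameters (logits for π, Cholesky for
B, logs for σ, κ and the Weibull scale; survival covariates standardised
internally, with the centering shift absorbed exactly into the scale).
The optimiser is L-BFGS-B with an analytic gradient (posterior-weighted
score), at most 500 iterations, from a data-driven first start (pooled
polynomial fit split by per-course mean residual) plus seeded random
perturbations; the default is 10 starts, and the best optimum is kept.
Classes are relabelled after fitting so class 1 has the lowest
time-averaged mean trajectory. Model size is selected by BIC
(`−2ℓ + k·ln N`, N = courses) over a (classes × polynomial order) grid;
non-converged candidates are only accepted when no candidate converged.
Standard errors come from the observed information (central-difference
Hessian at the optimum, delta-method to the natural scale); the Weibull
shape and the log-time effects are partially collinear over realistic
follow-up, so their standard errors are honestly large.

Degenerate inputs: courses need at least one DAS28 observation and a
strictly positive event/censoring time; a non-positive-definite marginal
covariance raises; hazard exponents are clipped at 700 before
exponentiation inside the optimiser so wild intermediate iterates cannot
overflow.

## Validation

Discrimination is the pooled Mann–Whitney AUC over all landmark
predictions (one row per prediction, no per-patient reweighting); ties
count ½. Outcome labels: *flare* if the first flare falls in `(s, s+13]`,
*no-flare* if flare-free follow-up covers `s+13`, *indeterminate* (excluded
from all metrics, not counted as negative) if the course is censored inside
the horizon. Cutoffs maximise Youden's J with classification rule
`risk ≥ cutoff`, ties toward the lower cutoff. Performance tables use a
patient-level nonparametric bootstrap (B = 1000, percentile 2.5/97.5).
Calibration groups predictions by predicted-risk quartiles and compares
mean predicted risk with observed flare frequency.

## Tapering simulation

The simulator replays an observed protocolised tapering course under
prediction-aided rules at a risk cutoff (`high` iff risk ≥ cutoff):

1. flares at or before the first high-risk visit are copied; the dose
   follows the trial (the prediction could not have acted);
2. at the first high-risk visit with no prior flare, the dose freezes at
   the level in force going into that visit (full dose at month 0) and
   later flares are suppressed except via rule 4;
3. if the course had already discontinued, the dose is raised to and kept
   at 50% of the full dose (the last tapering step) instead;
4. a later observed flare is copied iff the dose under which it developed
   (the dose in force over the interval ending at the flare visit) is at or
   above the simulated dose; the simulation then follows the trial for the
   rest of follow-up. A flare whose reinstatement/escalation response lifts
   the trial dose above the frozen simulated level is copied as well — this
   closes the one edge (persistent-flare escalation to full dose) in which
   the dose-dominance invariant would otherwise fail.

Two invariants are asserted on every simulated course: simulated flares
are a multiset-subset of observed flares, and the simulated dose is at or
above the observed dose at every visit. Outcomes over the 18-month window:
mean flares per patient, proportion with ≥ 1 flare, and the time-weighted
mean dose fraction (doses persist between 3-monthly visits), with
patient-bootstrap CIs. Trade-off ratios between two strategies are
Δdose/Δflares ("dose given back per flare prevented") and its reciprocal,
both invariant under swapping the arms and undefined (NaN, flagged) for
identical arms.

## Synthetic cohorts

The generators draw from the model above, so every pipeline stage can be
tested against known ground truth.

* **Published quantities used as defaults**: class split 182/97; hazard
  ratios for the class time effects (1.04, 1.66; 1.14, 4.52 — read as per
  year and per year²), the eight covariate effects (0.97/week … 2.51) and
  the dose ≤ 50% effect (2.21), taken as the log-HR truth; covariate
  marginals (seropositivity 84.6%/85.4%, disease duration median 9/6
  years, DAS28-interval mean 22.3 weeks SD 12.3, follow-up median ~21
  months, time-to-LDA 42.1 ± 29.1 weeks for the trial arm); trial protocol
  100% → 67% → 50% → 0% at months 0/3/6, last effective dose reinstated on
  flare, full dose on a repeat flare, 18-month grid.
* **Calibrated, not published**: the Weibull scale ρ = 0.00172/week and a
  trial hazard multiplier of 1.76 were set once by bisection so the
  EHR-style cohort shows ≈ 0.47 flares per patient-year and the tapering
  arm ≈ 0.62 — the reported rates — and then frozen.
* **Chosen as plausible, not published**: trajectory coefficients (stable
  class ~2.2 flat; rising class from 2.5 to ≈ 4.2 DAS28 at 18 months),
  random-effect SDs (0.40 intercept, 0.004/week slope), residual SD 0.50,
  κ = 1, EHR taper attempt probability 0.15/visit. Covariates are mutually
  independent (only marginals are known).

Event times are drawn by inverse transform of the cumulative hazard on a
0.25-week grid, per inter-visit interval, conditional on survival since
the last renewal. The course's recorded first-flare time is the *true*
event time; the visit-level flare flag marks the next visit (where a
clinician would record it). Baseline DAS28 is drawn from the trajectory
model truncated at 3.2 (the LDA anchor) and doubles as the baseline-DAS28
covariate.

What the generators deliberately do **not** emulate: informative visit
scheduling, missing covariates, measurement-driven flare flags (the flags
are event-driven ground truth, not recomputed from noisy DAS28 pairs),
drug-specific pharmacokinetics, and between-patient frailty beyond class
and covariates. Passing tests therefore show that the pipeline recovers
the truth when its assumptions hold and degrades gracefully under the
visit-process realism included — not that the model is adequate for any
particular real cohort.

## Problem sizes and design choices in the checks

The recovery checks fit 2-class quadratic models on cohorts of 500 courses
over 10 seeded replicates, with BIC selection over 1–3 classes at the true
polynomial order; the prediction-consistency check cross-validates 1000
courses in 5 patient-level folds and compares with the oracle AUC computed
from the generating model's true risks; simulator invariants run on 1000
random trial courses. The end-to-end tapering check fits the model on an
independent 300-course cohort drawn from the same protocolised trial
process and applies it to the standard 121+59 trial. A model developed on
the EHR-style process instead transports with systematically lower
predicted risks (the two processes are calibrated to different flare
rates, 0.47 vs 0.62 per patient-year, and different covariate mixes), so a
fixed 35% cutoff rarely fires before the first flare — the same transport
gap that shows up as the development-vs-external cutoff discrepancy in
this literature. The end-to-end check therefore isolates the decision
mechanism under transportable predictions; transportability itself is
what the cross-validation/oracle-AUC check measures.

## Known limitations

* κ, γ1, γ2 (and δ when dose changes correlate with time) are mutually
  near-collinear over 18–24-month follow-up; point estimates of the hazard
  *shape* are unstable even when predicted risks are accurate.
* The class posterior at baseline rests on a single DAS28 value, so
  baseline predictions are close to the class prior (the motivation for
  the `include_baseline=False` option in validation).
* The renewal assumption after a flare is a modelling convenience; nothing
  in first-flare data identifies post-flare hazard.
* Bootstrap CIs treat the fitted model as fixed (no refitting inside the
  bootstrap), so they understate model-selection uncertainty.
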