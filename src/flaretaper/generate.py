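"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators share one ground-truth joint latent class model (latent-class
DAS28 trajectories linked to class-specific flare hazards):

* :func:`generate_development_cohort` - an EHR-style cohort with irregular
  visits (mean DAS28 interval ~22 weeks), sporadic clinician-driven
  tapering, a ~65/35 class split and a flare rate around 0.47 per
  patient-year;
* :func:`generate_trial_cohort` - a protocolised tapering trial: 3-monthly
  visits over 18 months, stepwise dose reduction 100% -> 67% -> 50% -> 0%
  with the last effective dose reinstated on flare (full dose on persistent
  flare), a disease-activity-guided arm and a routine-care arm, flare rate
  around 0.62 per patient-year in the tapering arm.

Covariate marginals default to the development-cohort summaries
(seropositivity 84.6%, disease duration median 9 years, ...); correlations
default to independence.  The hazard scale is calibrated to the target
flare rates (true scale parameters are not published); every draw is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CourseCovariates, PatientCourse, VisitRecord
from .jlcm import (
    JlcmParameters,
    ModelSpec,
    WEEKS_PER_YEAR,
    cumulative_hazard,
    dose_segments,
)
from .tapering import TRIAL_MONTHS, TrialCourse

__all__ = [
    "GeneratorConfig",
    "truth_parameters",
    "generate_development_cohort",
    "generate_trial_cohort",
    "true_risk",
    "trial_course_view",
    "TAPER_LEVELS",
]

#: protocol dose levels: full, two taper steps, discontinuation
TAPER_LEVELS = (1.0, 2.0 / 3.0, 0.5, 0.0)

#: trial visit grid in weeks (3 months = 13 weeks)
TRIAL_WEEKS = tuple(13.0 * k for k in range(len(TRIAL_MONTHS)))


@dataclass
class GeneratorConfig:
    """Ground-truth parameters and sampling design of the synthetic cohorts.

    Trajectory/hazard defaults follow the final two-class quadratic model:
    a stable low-activity class (~65%) and a rising-activity class (~35%)
    whose log-hazard time effects and covariate log-hazard effects are the
    logs of the published hazard ratios (per year / per year^2 for the time
    terms).  The Weibull scale ``rho`` and the trial hazard multiplier are
    calibrated to the target flare rates of 0.47 (EHR) and 0.62 (trial
    tapering arm) per patient-year.
    """

    n_courses: int = 279
    class_probs: tuple[float, ...] = (182 / 279, 97 / 279)
    # trajectory fixed effects (DAS28 units per week^k), one row per class
    beta: tuple[tuple[float, ...], ...] = (
        (2.20, 0.0005, 0.0),
        (2.50, 0.0100, 0.000150),
    )
    re_sd_intercept: float = 0.40
    re_sd_slope: float = 0.004      # DAS28 per week
    residual_sd: float = 0.50
    kappa: float = 1.0
    rho: float = 0.00172            # per week; calibrated to 0.47 flares/py
    gamma1: tuple[float, ...] = (0.0392, 0.1310)   # ln(1.04), ln(1.14) per year
    gamma2: tuple[float, ...] = (0.5068, 1.5085)   # ln(1.66), ln(4.52) per year^2
    beta_surv: tuple[float, ...] = (
        -0.03046,  # time to reach LDA, per week          (HR 0.97)
        0.16551,   # DAS28 at baseline                    (HR 1.18)
        0.19062,   # dose fraction at baseline            (HR 1.21)
        0.54232,   # SJC increase at baseline             (HR 1.72)
        0.72755,   # TJC increase at baseline             (HR 2.07)
        0.01980,   # disease duration, per year           (HR 1.02)
        0.92028,   # seropositivity                       (HR 2.51)
        -0.10536,  # TNFi type                            (HR 0.90)
    )
    delta: float = 0.79299          # dose <= 50% indicator (HR 2.21)
    # EHR visit process and follow-up
    visit_interval_mean: float = 22.3
    visit_interval_sd: float = 12.3
    min_visit_gap: float = 2.0
    followup_median: float = 91.0   # weeks (~21 months)
    followup_log_sd: float = 0.25
    followup_range: tuple[float, float] = (30.0, 156.0)
    taper_prob: float = 0.15        # clinician taper attempt per visit (EHR)
    # covariate marginals
    seropositive_rate: float = 0.846
    duration_log_median: float = np.log(9.0)
    duration_log_sd: float = 0.885
    time_to_lda_mean: float = 30.0
    time_to_lda_sd: float = 15.0
    tj_increase_rate: float = 0.176
    sj_increase_rate: float = 0.100
    tnfi_rate: float = 0.78
    baseline_das28_mean: float = 2.6
    baseline_das28_sd: float = 0.5
    # trial design
    n_dgdo: int = 121
    n_routine: int = 59
    trial_hazard_scale: float = 1.76  # calibrated to 0.62 flares/py (DGDO)
    trial_seropositive_rate: float = 0.854
    trial_duration_log_median: float = np.log(6.0)
    trial_time_to_lda_mean: float = 42.1
    trial_time_to_lda_sd: float = 29.1
    trial_baseline_das28_mean: float = 2.15
    trial_baseline_das28_sd: float = 0.55

    def validate(self) -> None:
        if self.n_courses < 1:
            raise ValueError("n_courses must be >= 1")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or min(self.class_probs) <= 0:
            raise ValueError("class_probs must be positive and sum to 1")
        if min(self.residual_sd, self.re_sd_intercept, self.re_sd_slope) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.kappa <= 0 or self.rho <= 0:
            raise ValueError("kappa and rho must be positive")

    def truth(self, hazard_scale: float = 1.0) -> JlcmParameters:
        return truth_parameters(self, hazard_scale=hazard_scale)

    @property
    def n_classes(self) -> int:
        return len(self.class_probs)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            n_classes=self.n_classes,
            poly_order=len(self.beta[0]) - 1,
        )


def truth_parameters(config: GeneratorConfig, hazard_scale: float = 1.0) -> JlcmParameters:
    """Ground-truth model parameters implied by a generator config."""
    config.validate()
    B = np.diag([config.re_sd_intercept ** 2, config.re_sd_slope ** 2])
    return JlcmParameters(
        pi=np.asarray(config.class_probs, dtype=float),
        beta=np.asarray(config.beta, dtype=float),
        B=B,
        sigma2=config.residual_sd ** 2,
        kappa=config.kappa,
        rho=config.rho * hazard_scale ** (1.0 / config.kappa),
        gamma1=np.asarray(config.gamma1, dtype=float),
        gamma2=np.asarray(config.gamma2, dtype=float),
        beta_surv=np.asarray(config.beta_surv, dtype=float),
        delta=config.delta,
    )


# ---------------------------------------------------------------------------
# event-time sampling
# ---------------------------------------------------------------------------

def _grid_cumhaz(params: JlcmParameters, g: int, eta: float,
                 dose_times: np.ndarray, dose_vals: np.ndarray,
                 t_max: float, step: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative hazard on a fine grid over (0, t_max], trapezoid rule.

    The dose in force at ``t`` is ``dose_vals[searchsorted(dose_times, t) - 1]``.
    """
    n = max(int(np.ceil(t_max / step)), 2)
    t = np.linspace(1e-6, t_max, n)
    idx = np.clip(np.searchsorted(dose_times, t, side="right") - 1, 0, None)
    le50 = (dose_vals[idx] <= 0.5).astype(float)
    tyr = t / WEEKS_PER_YEAR
    logh = (
        np.log(params.kappa) + params.kappa * np.log(params.rho)
        + (params.kappa - 1.0) * np.log(t)
        + params.gamma1[g] * tyr + params.gamma2[g] * tyr ** 2
        + params.delta * le50 + eta
    )
    h = np.exp(logh)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(t))])
    return t, cum


def _sample_event_in_window(
    rng: np.random.Generator, params: JlcmParameters, g: int, eta: float,
    dose_times: np.ndarray, dose_vals: np.ndarray,
    renewal: float, t0: float, t1: float, step: float = 0.25,
) -> Optional[float]:
    """Draw an event in absolute window ``(t0, t1]`` conditional on no event
    since ``renewal``, on the renewal hazard clock (hazard time runs from the
    last flare; the dose is evaluated on the absolute clock).

    Returns the absolute event time or None.
    """
    tau0, tau1 = max(t0 - renewal, 0.0), t1 - renewal
    if tau1 <= tau0:
        return None
    n = max(int(np.ceil((tau1 - tau0) / step)), 2)
    tau = np.linspace(max(tau0, 1e-6), tau1, n)
    t_abs = tau + renewal
    idx = np.clip(np.searchsorted(dose_times, t_abs, side="right") - 1, 0, None)
    le50 = (dose_vals[idx] <= 0.5).astype(float)
    tyr = tau / WEEKS_PER_YEAR
    logh = (
        np.log(params.kappa) + params.kappa * np.log(params.rho)
        + (params.kappa - 1.0) * np.log(tau)
        + params.gamma1[g] * tyr + params.gamma2[g] * tyr ** 2
        + params.delta * le50 + eta
    )
    h = np.exp(logh)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(tau))])
    target = rng.exponential()
    if target >= cum[-1]:
        return None
    return float(np.interp(target, cum, tau)) + renewal


# ---------------------------------------------------------------------------
# development (EHR-style) cohort
# ---------------------------------------------------------------------------

def _sample_covariates(rng: np.random.Generator, config: GeneratorConfig,
                       baseline_das28: float, baseline_dose: float) -> CourseCovariates:
    return CourseCovariates(
        seropositive=bool(rng.random() < config.seropositive_rate),
        disease_duration_years=float(rng.lognormal(config.duration_log_median,
                                                   config.duration_log_sd)),
        time_to_lda_weeks=float(max(rng.normal(config.time_to_lda_mean,
                                               config.time_to_lda_sd), 0.0)),
        das28_baseline=baseline_das28,
        dose_fraction_baseline=baseline_dose,
        tj_increase_baseline=bool(rng.random() < config.tj_increase_rate),
        sj_increase_baseline=bool(rng.random() < config.sj_increase_rate),
        tnfi=bool(rng.random() < config.tnfi_rate),
    )


def generate_development_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> tuple[list[PatientCourse], pd.DataFrame]:
    """Sample an EHR-style cohort plus its ground truth.

    Returns ``(courses, truth)`` where ``truth`` has one row per course with
    the latent class, random effects and true event times.  Flare flags are
    ground truth from the hazard (detected at the next visit); flares recur
    via a renewal assumption; on flare the previous dose level is reinstated
    at the next visit and tapering stops.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    params = config.truth()
    courses, rows = [], []
    for i in range(config.n_courses):
        g = int(rng.choice(config.n_classes, p=config.class_probs))
        b = rng.multivariate_normal(np.zeros(2), params.B)
        followup = float(np.clip(
            np.exp(np.log(config.followup_median) + config.followup_log_sd * rng.normal()),
            *config.followup_range,
        ))
        # visit schedule
        times = [0.0]
        while times[-1] < followup:
            gap = max(rng.gamma(
                (config.visit_interval_mean / config.visit_interval_sd) ** 2,
                config.visit_interval_sd ** 2 / config.visit_interval_mean,
            ), config.min_visit_gap)
            times.append(times[-1] + gap)
        times = [t for t in times if t <= followup]
        if len(times) < 2:
            times.append(followup)
        times = np.array(times)

        # dose path: sporadic clinician tapering; on flare the previous level
        # is reinstated at the detecting visit and tapering stops
        levels = list(TAPER_LEVELS)
        level_idx = int(rng.choice([0, 1, 2], p=[0.65, 0.20, 0.15]))
        baseline_dose = levels[level_idx]
        # baseline DAS28 follows the trajectory model, truncated at the LDA
        # threshold (the baseline is anchored at the first DAS28 <= 3.2)
        mean0 = float(params.beta[g, 0] + b[0])
        base_das = mean0 + rng.normal(0, config.residual_sd)
        for _ in range(50):
            if base_das <= 3.2:
                break
            base_das = mean0 + rng.normal(0, config.residual_sd)
        base_das = float(np.clip(base_das, 0.3, 3.2))
        cov = _sample_covariates(rng, config, baseline_das28=base_das,
                                 baseline_dose=baseline_dose)
        eta = float(cov.as_vector() @ params.beta_surv)

        doses = np.empty(len(times))
        doses[0] = baseline_dose
        tapering_stopped = False
        flare_visits: list[float] = []
        true_events: list[float] = []
        renewal = 0.0
        for k in range(1, len(times)):
            # event in the interval ending at this visit, under the dose path so far
            ev = _sample_event_in_window(
                rng, params, g, eta, times[:k], doses[:k],
                renewal=renewal, t0=float(times[k - 1]), t1=float(times[k]),
            )
            flared_now = ev is not None
            if flared_now:
                true_events.append(ev)
                flare_visits.append(float(times[k]))
                renewal = float(ev)  # at-risk clock restarts at the event
            # dose decision at this visit
            if flared_now:
                level_idx = max(level_idx - 1, 0)
                tapering_stopped = True
            elif not tapering_stopped and level_idx < len(levels) - 1 \
                    and rng.random() < config.taper_prob:
                level_idx += 1
            doses[k] = levels[level_idx]
        # observations
        T = np.vander(times, params.beta.shape[1], increasing=True)
        y = T @ params.beta[g] + b[0] + b[1] * times + rng.normal(0, config.residual_sd, len(times))
        y[0] = base_das
        visits = [
            VisitRecord(time=float(t), das28=float(max(yv, 0.1)),
                        dose_fraction=float(dv), flare=bool(t in flare_visits))
            for t, yv, dv in zip(times, y, doses)
        ]
        # event times are the true hazard event times; the visit flags mark
        # where a clinician would record the flare (next visit)
        course = PatientCourse(
            course_id=f"dev{i:04d}", patient_id=f"p{i:04d}",
            visits=visits, covariates=cov,
            first_flare_time=true_events[0] if true_events else None,
            censor_time=float(times[-1]),
            true_class=g, flare_times=[float(e) for e in true_events],
        )
        courses.append(course)
        rows.append({
            "course_id": course.course_id, "true_class": g,
            "b0": b[0], "b1": b[1],
            "n_flares": len(flare_visits),
            "first_event_time": true_events[0] if true_events else np.nan,
            "followup_weeks": times[-1],
        })
    return courses, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-style cohort
# ---------------------------------------------------------------------------

def _trial_covariates(rng: np.random.Generator, config: GeneratorConfig) -> CourseCovariates:
    return CourseCovariates(
        seropositive=bool(rng.random() < config.trial_seropositive_rate),
        disease_duration_years=float(rng.lognormal(config.trial_duration_log_median,
                                                   config.duration_log_sd)),
        time_to_lda_weeks=float(max(rng.normal(config.trial_time_to_lda_mean,
                                               config.trial_time_to_lda_sd), 0.0)),
        das28_baseline=float(np.clip(rng.normal(config.trial_baseline_das28_mean,
                                                config.trial_baseline_das28_sd), 0.3, 3.2)),
        dose_fraction_baseline=1.0,
        tj_increase_baseline=False,
        sj_increase_baseline=False,
        tnfi=True,
    )


def generate_trial_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
) -> tuple[list[PatientCourse], pd.DataFrame]:
    """Sample a protocolised tapering trial (tapering + routine-care arms).

    DGDO-arm courses step down 100% -> 67% -> 50% -> 0% at months 0/3/6
    unless a flare intervenes; on flare the last effective dose is
    reinstated at the flare visit and tapering stops; a further flare
    escalates to the full dose.  Routine care keeps the full dose.  Flares
    are drawn from the class-specific hazard (which responds to the
    dose <= 50% indicator) on a renewal clock and recorded at the end-of-
    interval visit.  Returns courses (with ``true_class`` set) and a truth
    table.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    params = config.truth(hazard_scale=config.trial_hazard_scale)
    weeks = np.array(TRIAL_WEEKS)
    courses, rows = [], []
    n_total = config.n_dgdo + config.n_routine
    for i in range(n_total):
        arm = "DGDO" if i < config.n_dgdo else "routine"
        g = int(rng.choice(config.n_classes, p=config.class_probs))
        b = rng.multivariate_normal(np.zeros(2), params.B)
        cov = _trial_covariates(rng, config)
        # baseline DAS28 from the trajectory model, truncated at LDA
        mean0 = float(params.beta[g, 0] + b[0])
        y0 = mean0 + rng.normal(0, config.residual_sd)
        for _ in range(50):
            if y0 <= 3.2:
                break
            y0 = mean0 + rng.normal(0, config.residual_sd)
        cov = dc_replace(cov, das28_baseline=float(np.clip(y0, 0.3, 3.2)))
        eta = float(cov.as_vector() @ params.beta_surv)

        doses = np.empty(len(weeks))
        flare_weeks: list[float] = []
        renewal = 0.0
        level_idx = 0
        flared = False
        persistent = False
        for k in range(len(weeks) - 1):
            if arm == "DGDO" and not flared and level_idx < len(TAPER_LEVELS) - 1:
                level_idx += 1  # planned taper step at this visit
            doses[k] = TAPER_LEVELS[level_idx] if arm == "DGDO" else 1.0
            ev = _sample_event_in_window(
                rng, params, g, eta, weeks[: k + 1], doses[: k + 1],
                renewal=renewal, t0=float(weeks[k]), t1=float(weeks[k + 1]),
            )
            if ev is not None:
                flare_weeks.append(float(weeks[k + 1]))
                renewal = float(weeks[k + 1])
                if arm == "DGDO":
                    if flared:
                        persistent = True
                        level_idx = 0          # escalate to full dose
                    else:
                        level_idx = max(level_idx - 1, 0)  # last effective dose
                    flared = True
        doses[-1] = TAPER_LEVELS[level_idx] if arm == "DGDO" else 1.0

        T = np.vander(weeks, params.beta.shape[1], increasing=True)
        y = T @ params.beta[g] + b[0] + b[1] * weeks + rng.normal(0, config.residual_sd, len(weeks))
        y[0] = cov.das28_baseline
        visits = [
            VisitRecord(time=float(t), das28=float(max(yv, 0.1)),
                        dose_fraction=float(d), flare=bool(t in flare_weeks))
            for t, yv, d in zip(weeks, y, doses)
        ]
        course = PatientCourse(
            course_id=f"{arm.lower()}{i:04d}", patient_id=f"t{i:04d}",
            visits=visits, covariates=cov,
            first_flare_time=flare_weeks[0] if flare_weeks else None,
            censor_time=float(weeks[-1]),
            true_class=g, flare_times=list(flare_weeks),
        )
        courses.append(course)
        rows.append({
            "course_id": course.course_id, "arm": arm, "true_class": g,
            "n_flares": len(flare_weeks), "persistent_flare": persistent,
        })
    return courses, pd.DataFrame(rows)


def trial_course_view(course: PatientCourse, risk: Optional[np.ndarray] = None,
                      arm: Optional[str] = None) -> TrialCourse:
    """View a 3-monthly trial course as a :class:`TrialCourse` for the
    tapering simulator (weeks -> months, per-visit doses and flares)."""
    weeks = np.array([v.time for v in course.visits])
    if len(weeks) != len(TRIAL_MONTHS) or not np.allclose(weeks, TRIAL_WEEKS):
        raise ValueError("course is not on the 18-month 3-monthly grid")
    months = np.array(TRIAL_MONTHS, dtype=float)
    flare_months = tuple(float(months[np.argmin(np.abs(weeks - fw))])
                         for fw in course.flare_times)
    return TrialCourse(
        course_id=course.course_id,
        dose=np.array([v.dose_fraction for v in course.visits]),
        flare_months=flare_months,
        risk=risk,
        arm=arm or ("routine" if course.course_id.startswith("routine") else "DGDO"),
    )


def true_risk(
    params: JlcmParameters,
    course: PatientCourse,
    s: float,
    h: float = 13.0,
    renewal_origin: float = 0.0,
) -> float:
    """Generating-model probability of a flare in ``(s, s+h]``.

    Uses the course's true latent class (no posterior) and its recorded dose
    path; the at-risk clock starts at ``renewal_origin``.
    """
    if course.true_class is None:
        raise ValueError("course has no ground-truth class")
    g = course.true_class
    eta = float(course.covariates.as_vector() @ params.beta_surv)
    tau0 = s - renewal_origin
    segs = dose_segments(course.dose_change_times() - renewal_origin,
                         lambda u: course.dose_at(u + renewal_origin),
                         tau0, tau0 + h)
    dlam = cumulative_hazard(params, g, segs, eta)
    return float(1.0 - np.exp(-dlam))
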