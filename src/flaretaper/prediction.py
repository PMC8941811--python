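"""Landmark ("dynamic") flare-risk prediction.

At a landmark time ``s`` the fitted model is combined with the course's
observed DAS28 history, fixed covariates and dose path:

1. posterior class weights
   ``w_g(s) ∝ pi_g * f_long(history <= s | g) * S_g(s | x, dose path)``;
2. predicted flare risk within horizon ``h``
   ``sum_g w_g(s) * (1 - exp(-(Lambda_g(s+h) - Lambda_g(s))))``
   with the cumulative hazard evaluated under the planned future dose path
   (by default the dose in force at ``s`` is carried forward).

Predictions after an earlier flare (needed when simulating 3-monthly
decisions) use a renewal assumption: the at-risk clock restarts at the last
flare, while the full DAS28 history still informs the class posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import PatientCourse
from .jlcm import (
    JLCMResults,
    cumulative_hazard,
    dose_segments,
    longitudinal_loglik_class,
)

__all__ = [
    "RiskPrediction",
    "posterior_class_at_landmark",
    "predict_flare_risk",
    "landmark_predictions",
    "predictions_frame",
]

#: label values for landmark outcomes
FLARE, NO_FLARE, INDETERMINATE = "flare", "no-flare", "indeterminate"


@dataclass(frozen=True)
class RiskPrediction:
    """One landmark prediction and its observed outcome label."""

    course_id: str
    patient_id: str
    landmark: float       # weeks
    horizon: float        # weeks
    risk: float           # P(flare in (s, s+h])
    label: str            # flare / no-flare / indeterminate
    at_baseline: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError(f"risk out of [0,1]: {self.risk}")
        if self.at_baseline != (self.landmark == 0.0):
            raise ValueError("at_baseline must hold exactly when landmark == 0")


def _dose_fn(course: PatientCourse, future: Optional[Callable[[float], float]], s: float):
    """Dose path: observed up to ``s``, ``future`` (or carried-forward) after."""
    if future is None:
        return course.dose_at, course.dose_change_times()
    def fn(t):
        return future(t) if t > s else course.dose_at(t)
    # candidate change times: observed ones plus a fine scan of the future path
    grid = np.linspace(s, s + 60.0, 121)
    vals = np.array([future(t) for t in grid])
    fut_changes = grid[1:][np.diff(vals) != 0]
    return fn, np.concatenate([course.dose_change_times(), fut_changes])


def _cum_hazard(fitted: JLCMResults, g: int, course: PatientCourse, t0: float, t1: float,
                eta: float, origin: float, dose_fn, change_times) -> float:
    """Cumulative hazard over renewal-clock interval (t0, t1], with the dose
    evaluated on the absolute clock (shifted by ``origin``)."""
    segs = dose_segments(change_times - origin, lambda u: dose_fn(u + origin), t0, t1)
    return cumulative_hazard(fitted.params, g, segs, eta)


def posterior_class_at_landmark(
    course: PatientCourse,
    s: float,
    fitted: JLCMResults,
    renewal_origin: float = 0.0,
) -> np.ndarray:
    """Posterior class probabilities given history up to landmark ``s``.

    Combines the prior class shares, the marginal density of the DAS28
    observations up to ``s``, and the probability of having remained
    flare-free up to ``s`` (since ``renewal_origin``) under each class.
    With no observations by ``s`` the longitudinal factor drops out and the
    weights reduce to the survival-weighted prior.
    """
    p = fitted.params
    G = fitted.spec.n_classes
    eta = float(course.covariates.as_vector() @ p.beta_surv)
    dose_fn, changes = course.dose_at, course.dose_change_times()
    logw = np.log(p.pi).copy()
    t_obs, _ = course.observations(up_to=s)
    for g in range(G):
        if len(t_obs) > 0:
            logw[g] += longitudinal_loglik_class(course, g, p, up_to=s)
        logw[g] -= _cum_hazard(fitted, g, course, 0.0, s - renewal_origin, eta,
                               renewal_origin, dose_fn, changes)
    total = logsumexp(logw)
    if not np.isfinite(total):
        raise ValueError("course not at risk: zero survival in every class")
    return np.exp(logw - total)


def predict_flare_risk(
    course: PatientCourse,
    s: float,
    fitted: JLCMResults,
    h: Optional[float] = None,
    future_dose: Optional[Callable[[float], float]] = None,
    renewal_origin: float = 0.0,
) -> float:
    """Probability of a flare within ``(s, s+h]`` given history up to ``s``.

    ``future_dose`` maps absolute time (weeks) to the planned dose fraction
    over the horizon.  By default the course's recorded dose path is used
    (which on a protocolised course is the next planned taper step), with
    the last recorded dose carried forward beyond the record.
    """
    if h is None:
        h = fitted.spec.horizon
    p = fitted.params
    w = posterior_class_at_landmark(course, s, fitted, renewal_origin=renewal_origin)
    if future_dose is None:
        dose_fn, changes = course.dose_at, course.dose_change_times()
    else:
        dose_fn, changes = _dose_fn(course, future_dose, s)
    risk = 0.0
    tau0 = s - renewal_origin
    for g in range(fitted.spec.n_classes):
        eta = float(course.covariates.as_vector() @ p.beta_surv)
        dlam = _cum_hazard(fitted, g, course, tau0, tau0 + h, eta,
                           renewal_origin, dose_fn, changes)
        risk += w[g] * (1.0 - np.exp(-dlam))
    return float(min(max(risk, 0.0), 1.0))


def _label(course: PatientCourse, s: float, h: float) -> str:
    if course.first_flare_time is not None and s < course.first_flare_time <= s + h:
        return FLARE
    if course.censor_time >= s + h:
        return NO_FLARE
    return INDETERMINATE


def landmark_predictions(
    courses: Iterable[PatientCourse],
    fitted: JLCMResults,
    include_baseline: bool = True,
    horizon: Optional[float] = None,
) -> list[RiskPrediction]:
    """One prediction per eligible visit of each course.

    A visit at time ``s`` is eligible when the course is still flare-free and
    in follow-up at ``s`` (``s`` before the first flare and before
    censoring).  The outcome label is *flare* if the first flare falls in
    ``(s, s+h]``, *no-flare* if follow-up covers ``s+h`` without one, and
    *indeterminate* (excluded from metrics) if the course is censored inside
    the horizon.
    """
    h = horizon if horizon is not None else fitted.spec.horizon
    out = []
    for c in courses:
        t_obs, _ = c.observations()
        for s in t_obs:
            s = float(s)
            if s == 0.0 and not include_baseline:
                continue
            if c.first_flare_time is not None and s >= c.first_flare_time:
                continue
            if s >= c.censor_time:
                continue
            risk = predict_flare_risk(c, s, fitted, h=h)
            out.append(RiskPrediction(
                course_id=c.course_id, patient_id=c.patient_id,
                landmark=s, horizon=h, risk=risk,
                label=_label(c, s, h), at_baseline=(s == 0.0),
            ))
    return out


def visit_risk_profile(
    course: PatientCourse,
    fitted: JLCMResults,
    horizon: Optional[float] = None,
) -> np.ndarray:
    """Predicted flare risk at every visit of a course, flares included.

    Needed by the tapering simulator, which consults the model at every
    3-monthly visit even after an earlier flare: the at-risk clock restarts
    at the most recent flare strictly before the visit (renewal), while the
    DAS28 history keeps informing the class posterior.
    """
    h = horizon if horizon is not None else fitted.spec.horizon
    risks = []
    for v in course.visits:
        s = float(v.time)
        origin = max((f for f in course.flare_times if f < s), default=0.0)
        risks.append(predict_flare_risk(course, s, fitted, h=h, renewal_origin=origin))
    return np.array(risks)


def predictions_frame(preds: Sequence[RiskPrediction]) -> pd.DataFrame:
    """Predictions as a DataFrame (column layout of the predictions CSV)."""
    return pd.DataFrame(
        [{
            "course_id": p.course_id, "patient_id": p.patient_id,
            "landmark_week": p.landmark, "horizon_week": p.horizon,
            "risk": p.risk, "label": p.label, "at_baseline": int(p.at_baseline),
        } for p in preds]
    )
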