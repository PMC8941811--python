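"""Shared fixtures: tiny synthetic cohorts and hand-set model parameters."""

from __future__ import annotations

import numpy as np
import pytest

from flaretaper.cohort import CourseCovariates, PatientCourse, VisitRecord
from flaretaper.jlcm import JLCMResults, JlcmParameters, ModelSpec


def default_covariates(**overrides) -> CourseCovariates:
    base = dict(
        seropositive=True,
        disease_duration_years=9.0,
        time_to_lda_weeks=30.0,
        das28_baseline=2.5,
        dose_fraction_baseline=1.0,
        tj_increase_baseline=False,
        sj_increase_baseline=False,
        tnfi=True,
    )
    base.update(overrides)
    return CourseCovariates(**base)


def make_course(
    times,
    das28,
    doses=None,
    course_id="c0",
    patient_id="p0",
    first_flare=None,
    censor=None,
    covariates=None,
    true_class=None,
):
    times = list(times)
    das28 = list(das28)
    doses = list(doses) if doses is not None else [1.0] * len(times)
    visits = [
        VisitRecord(time=float(t), das28=(None if y is None else float(y)),
                    dose_fraction=float(d))
        for t, y, d in zip(times, das28, doses)
    ]
    censor = censor if censor is not None else (first_flare or times[-1])
    return PatientCourse(
        course_id=course_id, patient_id=patient_id, visits=visits,
        covariates=covariates or default_covariates(),
        first_flare_time=first_flare, censor_time=float(max(censor, times[-1]))
        if first_flare is None else float(censor),
        true_class=true_class,
        flare_times=[first_flare] if first_flare is not None else [],
    )


def make_results(params: JlcmParameters, spec: ModelSpec) -> JLCMResults:
    """Wrap hand-set parameters as a results object for prediction calls."""
    return JLCMResults(
        model=None, spec=spec, params=params, loglik=0.0,
        n_params=spec.n_params, bic=0.0, converged=True, n_starts_used=0,
        posterior=None,
    )


def exponential_params(rho: float = 0.01, ncov: int = 8) -> JlcmParameters:
    """G=1, constant hazard rho, no covariate or dose effects."""
    return JlcmParameters(
        pi=np.array([1.0]),
        beta=np.array([[2.4, 0.002, 0.0]]),
        B=np.diag([0.16, 1e-6]),
        sigma2=0.25,
        kappa=1.0,
        rho=rho,
        gamma1=np.zeros(1),
        gamma2=np.zeros(1),
        beta_surv=np.zeros(ncov),
        delta=0.0,
    )


def two_class_params() -> JlcmParameters:
    return JlcmParameters(
        pi=np.array([0.6, 0.4]),
        beta=np.array([[2.2, 0.001, 0.0], [2.8, 0.010, 0.0001]]),
        B=np.array([[0.16, 0.0002], [0.0002, 1e-5]]),
        sigma2=0.25,
        kappa=1.1,
        rho=0.004,
        gamma1=np.array([0.05, 0.2]),
        gamma2=np.array([0.3, 1.0]),
        beta_surv=np.array([-0.03, 0.17, 0.19, 0.54, 0.73, 0.02, 0.92, -0.11]),
        delta=0.79,
    )


def simulate_faithful_cohort(
    params: JlcmParameters,
    n: int = 200,
    seed: int = 0,
    visit_gap: float = 15.0,
    followup: float = 104.0,
    taper_half: bool = True,
    taper_week: float = 45.0,
    taper_dose: float = 0.4,
):
    """Model-faithful simulation: exact continuous event times drawn by
    inverse transform from the class hazard on a dense grid, observations
    from the exact longitudinal model.  Serves as ground truth for
    estimation tests (no detection delay, no truncation beyond baseline)."""
    rng = np.random.default_rng(seed)
    G = len(params.pi)
    courses = []
    for i in range(n):
        g = int(rng.choice(G, p=params.pi))
        b = rng.multivariate_normal(np.zeros(2), params.B)
        times = np.arange(0.0, followup + 1e-9, visit_gap)
        tapered = taper_half and (i % 2 == 0)
        doses = np.where((times >= taper_week) & tapered, taper_dose, 1.0)
        cov = default_covariates(
            seropositive=bool(rng.random() < 0.8),
            disease_duration_years=float(rng.lognormal(np.log(9.0), 0.6)),
            time_to_lda_weeks=float(max(rng.normal(30, 10), 0.0)),
            das28_baseline=float(np.clip(rng.normal(2.5, 0.4), 0.5, 3.2)),
            tj_increase_baseline=bool(rng.random() < 0.18),
            sj_increase_baseline=bool(rng.random() < 0.10),
        )
        eta = float(cov.as_vector() @ params.beta_surv)
        tg = np.linspace(1e-6, followup, 6000)
        le = ((tg >= taper_week) & tapered & (taper_dose <= 0.5)).astype(float)
        tyr = tg / 52.0
        logh = (np.log(params.kappa) + params.kappa * np.log(params.rho)
                + (params.kappa - 1.0) * np.log(tg)
                + params.gamma1[g] * tyr + params.gamma2[g] * tyr ** 2
                + params.delta * le + eta)
        h = np.exp(logh)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(tg))])
        E = rng.exponential()
        ev = float(np.interp(E, cum, tg)) if E < cum[-1] else None
        end = ev if ev is not None else followup
        keep = times <= end
        vt, vd = times[keep], doses[keep]
        k = params.beta.shape[1]
        T = np.vander(vt, k, increasing=True)
        y = T @ params.beta[g] + b[0] + b[1] * vt \
            + rng.normal(0, np.sqrt(params.sigma2), len(vt))
        y[0] = min(y[0], 3.2)
        visits = [VisitRecord(time=float(t), das28=float(max(v, 0.1)),
                              dose_fraction=float(d))
                  for t, v, d in zip(vt, y, vd)]
        courses.append(PatientCourse(
            course_id=f"c{i}", patient_id=f"p{i}", visits=visits,
            covariates=cov, first_flare_time=ev, censor_time=float(end),
            true_class=g, flare_times=[ev] if ev is not None else [],
        ))
    return courses


@pytest.fixture(scope="session")
def small_dev_cohort():
    from flaretaper.generate import GeneratorConfig, generate_development_cohort
    cfg = GeneratorConfig(n_courses=120)
    return generate_development_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def small_dev_fit(small_dev_cohort):
    from flaretaper.jlcm import JointLatentClassModel
    courses, _ = small_dev_cohort
    return JointLatentClassModel(courses, ModelSpec(2, 2)).fit(n_starts=2, seed=0)
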