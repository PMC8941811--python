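"""Joint latent class mixed model for DAS28 trajectories and flare hazard.

The model assumes the cohort is a finite mixture of ``G`` latent classes.
Conditional on class ``g``:

* the DAS28 of course ``i`` follows a polynomial mean trajectory
  ``beta_g(t)`` plus a course-level random intercept and slope
  ``(b0_i, b1_i) ~ N(0, B)`` (shared covariance across classes) and residual
  noise ``N(0, sigma^2)``;
* the time to first flare has hazard

  ``lambda_g(t) = kappa * rho^kappa * t^(kappa-1)
                  * exp(gamma1_g * t_yr + gamma2_g * t_yr^2
                        + x_i' beta_s + delta * 1[dose(t) <= 0.5])``

  i.e. a Weibull baseline shared across classes, class-specific log-linear
  and log-quadratic time effects (per year and per year^2), fixed baseline
  covariates, and a time-varying indicator for a biologic dose at or below
  half the registered dose.

Longitudinal and survival outcomes are conditionally independent given the
class; the random effects are integrated analytically out of the
longitudinal density.  Class membership is an intercept-only multinomial.
Estimation is maximum likelihood by multi-start quasi-Newton on transformed
parameters; model size (number of classes, polynomial order) is chosen by
BIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .cohort import PatientCourse, SURVIVAL_COVARIATES

__all__ = [
    "ModelSpec",
    "JlcmParameters",
    "JointLatentClassModel",
    "JLCMResults",
    "FitError",
    "InvalidParametersError",
    "longitudinal_loglik_class",
    "survival_loglik_class",
    "joint_loglik",
    "select_model",
    "log_hazard",
    "cumulative_hazard",
    "dose_segments",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 52.0

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


class FitError(RuntimeError):
    """No optimisation start converged."""


class InvalidParametersError(ValueError):
    """Parameters outside the model's admissible set."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of one candidate model."""

    n_classes: int = 2
    poly_order: int = 2
    horizon: float = 13.0  # weeks ("3 months")
    include_time_varying_dose: bool = True
    survival_covariates: tuple[str, ...] = SURVIVAL_COVARIATES

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")

    @property
    def n_params(self) -> int:
        G, k = self.n_classes, self.poly_order + 1
        n = (G - 1) + G * k + 3 + 1 + 2 + 2 * G + len(self.survival_covariates)
        if self.include_time_varying_dose:
            n += 1
        return n


@dataclass
class JlcmParameters:
    """Natural-scale parameters of a joint latent class model."""

    pi: np.ndarray          # (G,) class probabilities
    beta: np.ndarray        # (G, poly_order+1) trajectory fixed effects
    B: np.ndarray           # (2,2) random intercept/slope covariance
    sigma2: float           # residual variance
    kappa: float            # Weibull shape
    rho: float              # Weibull scale (per week)
    gamma1: np.ndarray      # (G,) log-hazard linear time effect, per year
    gamma2: np.ndarray      # (G,) log-hazard quadratic time effect, per year^2
    beta_surv: np.ndarray   # (ncov,) covariate log-hazard effects
    delta: float = 0.0      # log-HR of dose <= 50% of full dose

    def validate(self) -> None:
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise InvalidParametersError("class probabilities must be positive and sum to 1")
        if self.sigma2 <= 0 or self.kappa <= 0 or self.rho <= 0:
            raise InvalidParametersError("sigma2, kappa, rho must be positive")
        eig = np.linalg.eigvalsh(self.B)
        if np.any(eig < -1e-10):
            raise InvalidParametersError("B must be positive semi-definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "JlcmParameters":
        return cls(
            pi=np.asarray(d["pi"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            B=np.asarray(d["B"], dtype=float),
            sigma2=float(d["sigma2"]),
            kappa=float(d["kappa"]),
            rho=float(d["rho"]),
            gamma1=np.asarray(d["gamma1"], dtype=float),
            gamma2=np.asarray(d["gamma2"], dtype=float),
            beta_surv=np.asarray(d["beta_surv"], dtype=float),
            delta=float(d["delta"]),
        )


# ---------------------------------------------------------------------------
# hazard primitives
# ---------------------------------------------------------------------------

def log_hazard(params: JlcmParameters, g: int, t, le50, eta: float = 0.0):
    """Log flare hazard of class ``g`` at time ``t`` (weeks).

    ``le50`` is the (0/1) indicator of dose <= 50%; ``eta`` the covariate
    linear predictor ``x' beta_surv``.
    """
    t = np.asarray(t, dtype=float)
    tyr = t / WEEKS_PER_YEAR
    return (
        np.log(params.kappa) + params.kappa * np.log(params.rho)
        + (params.kappa - 1.0) * np.log(t)
        + params.gamma1[g] * tyr + params.gamma2[g] * tyr ** 2
        + params.delta * np.asarray(le50, dtype=float) + eta
    )


def dose_segments(change_times: np.ndarray, dose_fn, t0: float, t1: float):
    """Split ``(t0, t1]`` into constant-dose segments ``(a, b, le50)``.

    ``change_times`` are candidate dose-change times; ``dose_fn`` evaluates
    the dose fraction in force at a time.
    """
    if t1 <= t0:
        return []
    cuts = [t0] + [float(t) for t in np.sort(change_times) if t0 < t < t1] + [t1]
    segs = []
    for a, b in zip(cuts, cuts[1:]):
        mid = 0.5 * (a + b)
        segs.append((a, b, 1.0 if float(dose_fn(mid)) <= 0.5 else 0.0))
    return segs


def cumulative_hazard(
    params: JlcmParameters, g: int, segments, eta: float = 0.0
) -> float:
    """Integral of the class-``g`` hazard over piecewise-constant-dose
    ``segments``, by 15-node Gauss-Legendre quadrature per segment."""
    total = 0.0
    for a, b, le50 in segments:
        if b <= a:
            continue
        half = 0.5 * (b - a)
        t = half * _GL_NODES + 0.5 * (a + b)
        total += half * np.sum(_GL_WEIGHTS * np.exp(log_hazard(params, g, t, le50, eta)))
    return total


def _course_eta(course: PatientCourse, params: JlcmParameters) -> float:
    return float(course.covariates.as_vector() @ params.beta_surv)


def _course_segments(course: PatientCourse, t0: float, t1: float):
    return dose_segments(course.dose_change_times(), course.dose_at, t0, t1)


# ---------------------------------------------------------------------------
# per-course log-likelihood contributions
# ---------------------------------------------------------------------------

def _poly_design(t: np.ndarray, order: int) -> np.ndarray:
    return np.vander(t, order + 1, increasing=True)


def longitudinal_loglik_class(
    course: PatientCourse, g: int, params: JlcmParameters,
    up_to: Optional[float] = None,
) -> float:
    """Marginal multivariate-normal log-density of the course's DAS28 vector
    under class ``g`` (random intercept and slope integrated analytically)."""
    t, y = course.observations(up_to=up_to)
    if len(t) == 0:
        return 0.0
    order = params.beta.shape[1] - 1
    T = _poly_design(t, order)
    Z = T[:, :2]
    mean = T @ params.beta[g]
    cov = Z @ params.B @ Z.T + params.sigma2 * np.eye(len(t))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise InvalidParametersError("longitudinal covariance not positive definite")
    r = y - mean
    return float(-0.5 * (len(t) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(cov, r)))


def survival_loglik_class(course: PatientCourse, g: int, params: JlcmParameters) -> float:
    """Log-likelihood of the course's (first-flare time, event flag) pair
    under the class-``g`` hazard with its time-varying dose path."""
    T = course.event_time
    if T <= 0:
        raise ValueError("invalid event time: must be positive")
    eta = _course_eta(course, params)
    segs = _course_segments(course, 0.0, T)
    cum = cumulative_hazard(params, g, segs, eta)
    ll = -cum
    if course.event_observed:
        le50 = segs[-1][2] if segs else (1.0 if course.dose_at(T) <= 0.5 else 0.0)
        ll += float(log_hazard(params, g, T, le50, eta))
    return float(ll)


def joint_loglik(
    courses: Sequence[PatientCourse], params: JlcmParameters, spec: ModelSpec
) -> float:
    """Observed-data log-likelihood: log of the class mixture per course,
    summed over courses (log-sum-exp stabilised)."""
    data = CohortData(courses, spec)
    return float(data.loglik_matrix(params)[1].sum())


# ---------------------------------------------------------------------------
# vectorised cohort representation
# ---------------------------------------------------------------------------

class CohortData:
    """Sufficient statistics of a cohort, precomputed for fast likelihoods.

    The longitudinal contribution only needs per-course cross-products of
    the polynomial design with itself and the outcome (the marginal
    covariance is a rank-2 update of ``sigma^2 I``); the survival integral
    only needs fixed quadrature nodes per constant-dose segment.
    """

    def __init__(self, courses: Sequence[PatientCourse], spec: ModelSpec):
        self.courses = list(courses)
        self.spec = spec
        N = len(self.courses)
        if N == 0:
            raise ValueError("empty cohort")
        k = spec.poly_order + 1

        self.TtT = np.zeros((N, k, k))
        self.Tty = np.zeros((N, k))
        self.yty = np.zeros(N)
        self.nobs = np.zeros(N)
        self.X = np.zeros((N, len(spec.survival_covariates)))
        self.d = np.zeros(N)
        self.T_event = np.zeros(N)
        self.le50_event = np.zeros(N)

        node_t, node_w, node_le50, node_idx = [], [], [], []
        for i, c in enumerate(self.courses):
            t, y = c.observations()
            if len(t) == 0:
                raise ValueError(f"course {c.course_id}: no DAS28 observations")
            T = _poly_design(t, spec.poly_order)
            self.TtT[i] = T.T @ T
            self.Tty[i] = T.T @ y
            self.yty[i] = y @ y
            self.nobs[i] = len(t)
            self.X[i] = c.covariates.as_vector()
            self.d[i] = 1.0 if c.event_observed else 0.0
            Te = c.event_time
            if Te <= 0:
                raise ValueError(f"course {c.course_id}: invalid event time {Te}")
            self.T_event[i] = Te
            segs = _course_segments(c, 0.0, Te)
            self.le50_event[i] = segs[-1][2] if segs else 0.0
            for a, b, le50 in segs:
                half = 0.5 * (b - a)
                node_t.append(half * _GL_NODES + 0.5 * (a + b))
                node_w.append(half * _GL_WEIGHTS)
                node_le50.append(np.full(_GL_NODES.shape, le50))
                node_idx.append(np.full(_GL_NODES.shape, i, dtype=int))
        self.node_t = np.concatenate(node_t)
        self.node_w = np.concatenate(node_w)
        self.node_le50 = np.concatenate(node_le50)
        self.node_idx = np.concatenate(node_idx)
        self._node_tyr = self.node_t / WEEKS_PER_YEAR
        self._node_logt = np.log(self.node_t)
        self._Tyr_event = self.T_event / WEEKS_PER_YEAR
        self._logT_event = np.log(self.T_event)

        # standardisation of survival covariates (used by the optimiser)
        self.x_mean = self.X.mean(axis=0)
        self.x_sd = self.X.std(axis=0)
        self.x_sd[self.x_sd < 1e-12] = 1.0
        self.Xstd = (self.X - self.x_mean) / self.x_sd

        self.ZtZ = self.TtT[:, :2, :2]
        self.ZtT = self.TtT[:, :2, :]
        self.Zty = self.Tty[:, :2]

    @property
    def n_courses(self) -> int:
        return len(self.courses)

    # -- log-likelihood -----------------------------------------------------

    def _long_ll(self, params: JlcmParameters) -> np.ndarray:
        """(N, G) longitudinal log-likelihood matrix."""
        G = self.spec.n_classes
        s2 = params.sigma2
        B = params.B
        N = self.n_courses
        MB = self.ZtZ @ B
        A = np.broadcast_to(np.eye(2), (N, 2, 2)) + MB / s2
        detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        if np.any(detA <= 0):
            raise InvalidParametersError("invalid parameters: covariance not PD")
        invA = np.empty_like(A)
        invA[:, 0, 0] = A[:, 1, 1]
        invA[:, 1, 1] = A[:, 0, 0]
        invA[:, 0, 1] = -A[:, 0, 1]
        invA[:, 1, 0] = -A[:, 1, 0]
        invA /= detA[:, None, None]
        C = B @ invA  # (N,2,2) == (B^-1 + M/s2)^-1
        out = np.empty((N, G))
        const = self.nobs * np.log(2 * np.pi * s2) + np.log(detA)
        for g in range(G):
            bg = params.beta[g]
            rss = self.yty - 2.0 * self.Tty @ bg + np.einsum("i,nij,j->n", bg, self.TtT, bg)
            q = self.Zty - self.ZtT @ bg
            quad = rss / s2 - np.einsum("ni,nij,nj->n", q, C, q) / s2 ** 2
            out[:, g] = -0.5 * (const + quad)
        return out

    def _surv_ll(self, params: JlcmParameters) -> np.ndarray:
        """(N, G) survival log-likelihood matrix."""
        G = self.spec.n_classes
        eta = self.X @ params.beta_surv
        logk = np.log(params.kappa)
        klogr = params.kappa * np.log(params.rho)
        base_nodes = (
            logk + klogr + (params.kappa - 1.0) * self._node_logt
            + params.delta * self.node_le50 + eta[self.node_idx]
        )
        base_event = (
            logk + klogr + (params.kappa - 1.0) * self._logT_event
            + params.delta * self.le50_event + eta
        )
        out = np.empty((self.n_courses, G))
        for g in range(G):
            expo = base_nodes + params.gamma1[g] * self._node_tyr + params.gamma2[g] * self._node_tyr ** 2
            cum = np.bincount(
                self.node_idx,
                weights=self.node_w * np.exp(np.clip(expo, None, 700.0)),
                minlength=self.n_courses,
            )
            loghaz = base_event + params.gamma1[g] * self._Tyr_event + params.gamma2[g] * self._Tyr_event ** 2
            out[:, g] = self.d * loghaz - cum
        return out

    def loglik_matrix(self, params: JlcmParameters) -> tuple[np.ndarray, np.ndarray]:
        """Per-course class terms and mixture log-likelihood.

        Returns ``(ll_mat, ll_i)`` where ``ll_mat[i, g] = log pi_g +
        longitudinal + survival log-likelihood`` and ``ll_i`` is its
        log-sum-exp over classes.
        """
        ll_mat = self._long_ll(params) + self._surv_ll(params) + np.log(params.pi)[None, :]
        return ll_mat, logsumexp(ll_mat, axis=1)

    def loglik(self, params: JlcmParameters) -> float:
        return float(self.loglik_matrix(params)[1].sum())

    def posterior(self, params: JlcmParameters) -> np.ndarray:
        ll_mat, ll_i = self.loglik_matrix(params)
        return np.exp(ll_mat - ll_i[:, None])


# ---------------------------------------------------------------------------
# parameter transformation (unconstrained <-> natural)
# ---------------------------------------------------------------------------

class _Transform:
    """Bijection between the natural parameters and an unconstrained vector.

    Variances, kappa and rho are log-transformed; B goes through its Cholesky
    factor; class probabilities through logits.  Survival covariates are
    standardised: the optimiser works with effects per SD, and the centering
    shift is absorbed into the Weibull scale (exact reparameterisation).
    """

    def __init__(self, spec: ModelSpec, x_mean: np.ndarray, x_sd: np.ndarray):
        self.spec = spec
        self.x_mean = x_mean
        self.x_sd = x_sd
        G, k = spec.n_classes, spec.poly_order + 1
        ncov = len(spec.survival_covariates)
        sizes = [G - 1, G * k, 3, 1, 2, G, G, ncov, 1 if spec.include_time_varying_dose else 0]
        self.slices = []
        ofs = 0
        for s in sizes:
            self.slices.append(slice(ofs, ofs + s))
            ofs += s
        self.n = ofs

    def pack(self, p: JlcmParameters) -> np.ndarray:
        G, k = self.spec.n_classes, self.spec.poly_order + 1
        th = np.zeros(self.n)
        sl = self.slices
        th[sl[0]] = np.log(p.pi[:-1]) - np.log(p.pi[-1])
        th[sl[1]] = p.beta.reshape(-1)
        L = np.linalg.cholesky(p.B + 1e-12 * np.eye(2))
        th[sl[2]] = [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]
        th[sl[3]] = [0.5 * np.log(p.sigma2)]
        beta_nat = p.beta_surv
        rho_int = p.rho * np.exp(float(self.x_mean @ beta_nat) / p.kappa)
        th[sl[4]] = [np.log(p.kappa), np.log(rho_int)]
        th[sl[5]] = p.gamma1
        th[sl[6]] = p.gamma2
        th[sl[7]] = beta_nat * self.x_sd
        if self.spec.include_time_varying_dose:
            th[sl[8]] = [p.delta]
        return th

    def unpack(self, th: np.ndarray) -> JlcmParameters:
        G, k = self.spec.n_classes, self.spec.poly_order + 1
        sl = self.slices
        logits = np.append(th[sl[0]], 0.0)
        pi = np.exp(logits - logsumexp(logits))
        a, b, c = th[sl[2]]
        L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        B = L @ L.T
        sigma2 = float(np.exp(2.0 * th[sl[3]][0]))
        kappa = float(np.exp(th[sl[4]][0]))
        rho_int = float(np.exp(th[sl[4]][1]))
        if sigma2 <= 0 or kappa <= 0 or rho_int <= 0 or not np.isfinite(kappa):
            raise InvalidParametersError("invalid parameters: scale underflow")
        beta_nat = th[sl[7]] / self.x_sd
        rho = rho_int * np.exp(-float(self.x_mean @ beta_nat) / kappa)
        delta = float(th[sl[8]][0]) if self.spec.include_time_varying_dose else 0.0
        return JlcmParameters(
            pi=pi,
            beta=th[sl[1]].reshape(G, k).copy(),
            B=B,
            sigma2=sigma2,
            kappa=kappa,
            rho=float(rho),
            gamma1=th[sl[5]].copy(),
            gamma2=th[sl[6]].copy(),
            beta_surv=beta_nat.copy(),
            delta=delta,
        )


def _natural_vector(p: JlcmParameters) -> tuple[list[str], np.ndarray]:
    """Flat named view of the natural parameters (for SE reporting)."""
    G, k = p.beta.shape
    names, vals = [], []
    for g in range(G):
        names.append(f"pi[{g+1}]"); vals.append(p.pi[g])
    for g in range(G):
        for j in range(k):
            names.append(f"beta[{g+1},t^{j}]"); vals.append(p.beta[g, j])
    names += ["B[0,0]", "B[0,1]", "B[1,1]", "sigma2", "kappa", "rho"]
    vals += [p.B[0, 0], p.B[0, 1], p.B[1, 1], p.sigma2, p.kappa, p.rho]
    for g in range(G):
        names.append(f"gamma1[{g+1}]"); vals.append(p.gamma1[g])
    for g in range(G):
        names.append(f"gamma2[{g+1}]"); vals.append(p.gamma2[g])
    for i, b in enumerate(p.beta_surv):
        names.append(f"beta_surv[{SURVIVAL_COVARIATES[i]}]"); vals.append(b)
    names.append("delta"); vals.append(p.delta)
    return names, np.array(vals)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class JointLatentClassModel:
    """Joint latent class mixed model bound to a cohort.

    Parameters
    ----------
    courses
        Assembled, eligible patient courses (complete covariates, at least
        one DAS28 observation, positive event/censoring time each).
    spec
        Structural model choices (number of classes, polynomial order, ...).
    """

    def __init__(self, courses: Sequence[PatientCourse], spec: ModelSpec = ModelSpec()):
        self.spec = spec
        self.data = CohortData(courses, spec)
        self._transform = _Transform(spec, self.data.x_mean, self.data.x_sd)

    # -- likelihood surface -------------------------------------------------

    def loglik(self, params: JlcmParameters) -> float:
        """Observed-data log-likelihood at ``params``."""
        return self.data.loglik(params)

    def _objective(self, th: np.ndarray) -> float:
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                val = -self.data.loglik(self._transform.unpack(th))
        except (InvalidParametersError, FloatingPointError, OverflowError):
            return 1e10
        if not np.isfinite(val):
            return 1e10
        return val

    def _objective_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative log-likelihood and its analytic gradient in the
        unconstrained parameterisation.

        The mixture gradient is the posterior-weighted sum of the per-class
        score contributions; longitudinal derivatives use the rank-2
        (Woodbury) structure, survival derivatives reuse the quadrature
        nodes of the cumulative hazard.
        """
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                return self._objective_grad_inner(th)
        except (InvalidParametersError, FloatingPointError, OverflowError,
                np.linalg.LinAlgError):
            return 1e10, np.zeros_like(th)

    def _objective_grad_inner(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        tr = self._transform
        d = self.data
        spec = self.spec
        p = tr.unpack(th)
        G, k = spec.n_classes, spec.poly_order + 1
        N = d.n_courses
        s2 = p.sigma2
        sl = tr.slices

        # ---- longitudinal pieces (shared across classes)
        M = d.ZtZ                                  # (N,2,2)
        MB = M @ p.B
        A = np.broadcast_to(np.eye(2), (N, 2, 2)) + MB / s2
        detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        if np.any(detA <= 0):
            raise InvalidParametersError("invalid parameters: covariance not PD")
        invA = np.empty_like(A)
        invA[:, 0, 0] = A[:, 1, 1]
        invA[:, 1, 1] = A[:, 0, 0]
        invA[:, 0, 1] = -A[:, 0, 1]
        invA[:, 1, 0] = -A[:, 1, 0]
        invA /= detA[:, None, None]
        C = p.B @ invA                             # (N,2,2), symmetric
        MC = np.einsum("nij,njk->nik", M, C)
        P = M / s2 - np.einsum("nij,njk->nik", MC, M) / s2 ** 2  # Z'Sigma^-1 Z
        trSinv = d.nobs / s2 - np.einsum("nii->n", MC) / s2 ** 2
        const = d.nobs * np.log(2 * np.pi * s2) + np.log(detA)

        ll_long = np.empty((N, G))
        grad_beta_g = np.empty((N, G, k))
        v_all = np.empty((N, G, 2))
        dsig2_all = np.empty((N, G))
        for g in range(G):
            bg = p.beta[g]
            rss = d.yty - 2.0 * d.Tty @ bg + np.einsum("i,nij,j->n", bg, d.TtT, bg)
            q = d.Zty - d.ZtT @ bg                 # (N,2)
            Cq = np.einsum("nij,nj->ni", C, q)
            quad = rss / s2 - np.einsum("ni,ni->n", q, Cq) / s2 ** 2
            ll_long[:, g] = -0.5 * (const + quad)
            # T' Sigma^-1 r
            Ttr = (d.Tty - np.einsum("nij,j->ni", d.TtT, bg)) / s2 \
                - np.einsum("nji,nj->ni", d.ZtT, Cq) / s2 ** 2
            grad_beta_g[:, g] = Ttr
            # v = Z' Sigma^-1 r
            v = q / s2 - np.einsum("nij,nj->ni", M, Cq) / s2 ** 2
            v_all[:, g] = v
            # r' Sigma^-2 r
            qCq = np.einsum("ni,ni->n", q, Cq)
            qCMCq = np.einsum("ni,nij,nj->n", Cq, M, Cq)
            rSSr = rss / s2 ** 2 - 2.0 * qCq / s2 ** 3 + qCMCq / s2 ** 4
            dsig2_all[:, g] = 0.5 * (rSSr - trSinv)

        # ---- survival pieces
        eta = d.X @ p.beta_surv
        logk = np.log(p.kappa)
        klogr = p.kappa * np.log(p.rho)
        logrho_int = th[sl[4]][1]
        base_nodes = (
            logk + klogr + (p.kappa - 1.0) * d._node_logt
            + p.delta * d.node_le50 + eta[d.node_idx]
        )
        base_event = (
            logk + klogr + (p.kappa - 1.0) * d._logT_event
            + p.delta * d.le50_event + eta
        )
        ll_surv = np.empty((N, G))
        cum_g = np.empty((N, G))
        dLam = {key: np.empty((N, G)) for key in ("g1", "g2", "delta", "logk")}
        for g in range(G):
            expo = base_nodes + p.gamma1[g] * d._node_tyr + p.gamma2[g] * d._node_tyr ** 2
            lam_w = d.node_w * np.exp(np.clip(expo, None, 700.0))
            cum = np.bincount(d.node_idx, weights=lam_w, minlength=N)
            cum_g[:, g] = cum
            loghaz = base_event + p.gamma1[g] * d._Tyr_event + p.gamma2[g] * d._Tyr_event ** 2
            ll_surv[:, g] = d.d * loghaz - cum
            dLam["g1"][:, g] = np.bincount(d.node_idx, weights=lam_w * d._node_tyr, minlength=N)
            dLam["g2"][:, g] = np.bincount(d.node_idx, weights=lam_w * d._node_tyr ** 2, minlength=N)
            dLam["delta"][:, g] = np.bincount(d.node_idx, weights=lam_w * d.node_le50, minlength=N)
            dLam["logk"][:, g] = np.bincount(
                d.node_idx,
                weights=lam_w * (1.0 + p.kappa * (logrho_int + d._node_logt)),
                minlength=N,
            )

        # ---- mixture
        ll_mat = ll_long + ll_surv + np.log(p.pi)[None, :]
        ll_i = logsumexp(ll_mat, axis=1)
        total = float(ll_i.sum())
        if not np.isfinite(total):
            return 1e10, np.zeros_like(th)
        W = np.exp(ll_mat - ll_i[:, None])          # posterior weights (N,G)

        grad = np.zeros_like(th)
        # class logits
        grad[sl[0]] = (W[:, :-1] - p.pi[None, :-1]).sum(axis=0)
        # trajectory fixed effects
        grad[sl[1]] = np.einsum("ng,ngk->gk", W, grad_beta_g).reshape(-1)
        # random-effects covariance via Cholesky
        Gmat = 0.5 * (
            np.einsum("ng,ngi,ngj->ij", W, v_all, v_all)
            - np.einsum("ng,nij->ij", W, P)
        )
        a, b, c = th[sl[2]]
        L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
        GL2 = 2.0 * Gmat @ L
        grad[sl[2]] = [GL2[0, 0] * L[0, 0], GL2[1, 0], GL2[1, 1] * L[1, 1]]
        # residual variance (theta holds log sigma)
        grad[sl[3]] = [float((W * dsig2_all).sum() * 2.0 * s2)]
        # survival: event-term derivatives
        Wd = W * d.d[:, None]
        dlogk_event = 1.0 + p.kappa * (logrho_int + d._logT_event)
        grad_logk = float((Wd * dlogk_event[:, None]).sum() - (W * dLam["logk"]).sum())
        grad_logrho = float(p.kappa * (Wd.sum() - (W * cum_g).sum()))
        grad[sl[4]] = [grad_logk, grad_logrho]
        grad[sl[5]] = (Wd * d._Tyr_event[:, None] - W * dLam["g1"]).sum(axis=0)
        grad[sl[6]] = (Wd * d._Tyr_event[:, None] ** 2 - W * dLam["g2"]).sum(axis=0)
        # covariates (standardised scale): d/d beta_std = Xstd * (d - Lambda)
        resid_surv = (Wd - W * cum_g).sum(axis=1)   # (N,)
        grad[sl[7]] = d.Xstd.T @ resid_surv
        if spec.include_time_varying_dose:
            grad[sl[8]] = [float((Wd * d.le50_event[:, None] - W * dLam["delta"]).sum())]
        return -total, -grad

    # -- starting values ----------------------------------------------------

    def _base_start(self) -> JlcmParameters:
        d = self.data
        G, k = self.spec.n_classes, self.spec.poly_order + 1
        # pooled polynomial least squares
        TtT = d.TtT.sum(axis=0)
        Tty = d.Tty.sum(axis=0)
        beta0 = np.linalg.solve(TtT + 1e-8 * np.eye(k), Tty)
        # per-course mean residual from the pooled fit (1' (y - T beta0) / n)
        resid_mean = (d.Tty[:, 0] - d.TtT[:, 0, :] @ beta0) / d.nobs
        beta = np.tile(beta0, (G, 1))
        if G > 1:
            # split courses by their mean residual level and refit per group
            qs = np.quantile(resid_mean, np.linspace(0, 1, G + 1))
            for g in range(G):
                lo, hi = qs[g], qs[g + 1]
                m = (resid_mean >= lo) & (resid_mean <= hi)
                if m.sum() >= 5:
                    beta[g] = np.linalg.solve(
                        d.TtT[m].sum(axis=0) + 1e-6 * np.eye(k), d.Tty[m].sum(axis=0)
                    )
                else:
                    beta[g, 0] = beta0[0] + (g - (G - 1) / 2)
        rss = d.yty.sum() - 2 * d.Tty.sum(axis=0) @ beta0 + beta0 @ TtT @ beta0
        s2 = max(rss / max(d.nobs.sum() - k, 1.0), 1e-3)
        rate = max(d.d.sum(), 0.5) / d.T_event.sum()
        return JlcmParameters(
            pi=np.full(G, 1.0 / G),
            beta=beta,
            B=np.diag([0.25 * s2 + 1e-3, 1e-5]),
            sigma2=0.75 * s2,
            kappa=1.0,
            rho=rate,
            gamma1=np.zeros(G),
            gamma2=np.zeros(G),
            beta_surv=np.zeros(len(self.spec.survival_covariates)),
            delta=0.0,
        )

    def _start_vectors(self, n_starts: int, seed: int) -> list[np.ndarray]:
        th0 = self._transform.pack(self._base_start())
        rng = np.random.default_rng(seed)
        starts = [th0]
        sl = self._transform.slices
        for _ in range(n_starts - 1):
            th = th0.copy()
            th[sl[0]] += rng.normal(0, 0.5, th[sl[0]].shape)
            pert = rng.normal(0, 0.3, th[sl[1]].shape)
            # perturb intercepts more than higher-order terms
            pert = pert * np.tile(0.5 ** np.arange(self.spec.poly_order + 1),
                                  self.spec.n_classes)
            th[sl[1]] += pert
            th[sl[3]] += rng.normal(0, 0.2)
            th[sl[4]] += rng.normal(0, 0.3, 2)
            th[sl[5]] += rng.normal(0, 0.3, th[sl[5]].shape)
            th[sl[6]] += rng.normal(0, 0.3, th[sl[6]].shape)
            th[sl[7]] += rng.normal(0, 0.2, th[sl[7]].shape)
            if self.spec.include_time_varying_dose:
                th[sl[8]] += rng.normal(0, 0.3)
            starts.append(th)
        return starts

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 10, seed: int = 0, maxiter: int = 500) -> "JLCMResults":
        """Maximise the joint likelihood from ``n_starts`` initialisations.

        The first start is a data-driven heuristic (pooled polynomial fit
        split by residual level); the rest are seeded random perturbations.
        Returns the best optimum found, with classes relabelled so class 1
        has the lowest time-averaged mean trajectory.
        """
        best = None
        n_converged = 0
        for th0 in self._start_vectors(n_starts, seed):
            res = minimize(
                self._objective_grad, th0, method="L-BFGS-B", jac=True,
                options={"maxiter": maxiter, "maxfun": 200 * maxiter},
            )
            conv = bool(res.success) and res.fun < 1e9
            if conv:
                n_converged += 1
            if res.fun < 1e9 and (best is None or res.fun < best[0].fun - 1e-9
                                  or (conv and not best[1] and res.fun < best[0].fun + 1e-6)):
                best = (res, conv)
        if best is None:
            raise FitError("fit failed: no start produced a finite likelihood")
        res, converged = best
        params = self._canonicalize(self._transform.unpack(res.x))
        loglik = -res.fun
        bic = -2.0 * loglik + self.spec.n_params * np.log(self.data.n_courses)
        posterior = self.data.posterior(params)
        return JLCMResults(
            model=self, spec=self.spec, params=params, loglik=loglik,
            n_params=self.spec.n_params, bic=float(bic), converged=converged,
            n_starts_used=n_starts, posterior=posterior,
            course_ids=[c.course_id for c in self.data.courses],
        )

    def _canonicalize(self, params: JlcmParameters) -> JlcmParameters:
        """Order classes by time-averaged mean trajectory (ascending), so the
        stable low-activity class is class 1."""
        tmax = float(self.data.T_event.max())
        k = params.beta.shape[1]
        weights = np.array([tmax ** j / (j + 1) for j in range(k)])
        avg = params.beta @ weights / tmax
        order = np.argsort(avg)
        params.pi = params.pi[order]
        params.beta = params.beta[order]
        params.gamma1 = params.gamma1[order]
        params.gamma2 = params.gamma2[order]
        return params


@dataclass
class JLCMResults:
    """Fitted joint latent class model.

    Carries the maximum-likelihood parameters, fit metadata and the posterior
    class membership of every course used in fitting.  Landmark risk
    prediction lives in :mod:`flaretaper.prediction` and is exposed here via
    :meth:`predict_risk` and :meth:`landmark_predictions`.
    """

    model: Optional[JointLatentClassModel]
    spec: ModelSpec
    params: JlcmParameters
    loglik: float
    n_params: int
    bic: float
    converged: bool
    n_starts_used: int
    posterior: Optional[np.ndarray]
    course_ids: list[str] = field(default_factory=list)
    selection_table: Optional[object] = None  # DataFrame set by select_model

    # -- prediction façade ----------------------------------------------------

    def predict_risk(self, course, s: float, horizon: Optional[float] = None, **kw) -> float:
        from .prediction import predict_flare_risk
        return predict_flare_risk(course, s, self, h=horizon or self.spec.horizon, **kw)

    def landmark_predictions(self, courses, include_baseline: bool = True, **kw):
        from .prediction import landmark_predictions
        return landmark_predictions(courses, self, include_baseline=include_baseline, **kw)

    # -- uncertainty ----------------------------------------------------------

    def standard_errors(self, eps: float = 1e-4):
        """Approximate standard errors of the natural-scale parameters.

        Inverts a central-difference Hessian of the negative log-likelihood
        at the optimum (observed information) and delta-methods through the
        parameter transformation.  Requires the fitting data (not available
        on a model loaded from JSON).  Weakly identified parameters show up
        as large standard errors.
        """
        import pandas as pd
        if self.model is None:
            raise ValueError("standard errors require the fitted model's data")
        tr = self.model._transform
        th = tr.pack(self.params)
        f = self.model._objective
        n = len(th)
        H = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = eps
                ej = np.zeros(n); ej[j] = eps
                H[i, j] = H[j, i] = (
                    f(th + ei + ej) - f(th + ei - ej) - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * eps * eps)
        cov_th = np.linalg.pinv(H)
        names, base = _natural_vector(self.params)
        J = np.zeros((len(base), n))
        for j in range(n):
            step = np.zeros(n); step[j] = eps
            _, up = _natural_vector(tr.unpack(th + step))
            _, dn = _natural_vector(tr.unpack(th - step))
            J[:, j] = (up - dn) / (2 * eps)
        var = np.einsum("ij,jk,ik->i", J, cov_th, J)
        return pd.Series(np.sqrt(np.maximum(var, 0.0)), index=names, name="se")

    # -- reporting ------------------------------------------------------------

    def parameter_table(self):
        """Named parameter estimates with hazard ratios where applicable."""
        import pandas as pd
        p = self.params
        rows = []
        G = self.spec.n_classes
        for g in range(G):
            rows.append((f"class {g+1} probability", p.pi[g], None))
        for g in range(G):
            for j in range(p.beta.shape[1]):
                rows.append((f"trajectory class {g+1}: t^{j} (DAS28/week^{j})", p.beta[g, j], None))
        rows += [
            ("random intercept variance", p.B[0, 0], None),
            ("random intercept-slope covariance", p.B[0, 1], None),
            ("random slope variance", p.B[1, 1], None),
            ("residual variance", p.sigma2, None),
            ("Weibull shape kappa", p.kappa, None),
            ("Weibull scale rho (per week)", p.rho, None),
        ]
        for g in range(G):
            rows.append((f"linear time coefficient, class {g+1} (per year)",
                         p.gamma1[g], np.exp(p.gamma1[g])))
            rows.append((f"quadratic time coefficient, class {g+1} (per year^2)",
                         p.gamma2[g], np.exp(p.gamma2[g])))
        for name, b in zip(self.spec.survival_covariates, p.beta_surv):
            rows.append((name, b, np.exp(b)))
        if self.spec.include_time_varying_dose:
            rows.append(("dose <= 50% of full dose (time-varying)", p.delta, np.exp(p.delta)))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "hazard_ratio"])

    def summary(self) -> str:
        lines = [
            "Joint latent class mixed model",
            f"  classes: {self.spec.n_classes}   polynomial order: {self.spec.poly_order}",
            f"  courses: {len(self.course_ids)}   parameters: {self.n_params}",
            f"  log-likelihood: {self.loglik:.3f}   BIC: {self.bic:.3f}",
            f"  converged: {self.converged} ({self.n_starts_used} starts)",
            "",
            self.parameter_table().to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    def class_shares(self) -> np.ndarray:
        """Share of courses assigned to each class by modal posterior."""
        if self.posterior is None:
            raise ValueError("posterior memberships unavailable (loaded model)")
        modal = self.posterior.argmax(axis=1)
        return np.bincount(modal, minlength=self.spec.n_classes) / len(modal)

    # -- serialization --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "spec": {
                "n_classes": self.spec.n_classes,
                "poly_order": self.spec.poly_order,
                "horizon": self.spec.horizon,
                "include_time_varying_dose": self.spec.include_time_varying_dose,
                "survival_covariates": list(self.spec.survival_covariates),
            },
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "JLCMResults":
        with open(path) as fh:
            payload = json.load(fh)
        s = payload["spec"]
        spec = ModelSpec(
            n_classes=s["n_classes"], poly_order=s["poly_order"], horizon=s["horizon"],
            include_time_varying_dose=s["include_time_varying_dose"],
            survival_covariates=tuple(s["survival_covariates"]),
        )
        return cls(
            model=None, spec=spec, params=JlcmParameters.from_dict(payload["params"]),
            loglik=payload["loglik"], n_params=payload["n_params"], bic=payload["bic"],
            converged=payload["converged"], n_starts_used=payload["n_starts_used"],
            posterior=None,
        )


def select_model(
    courses: Sequence[PatientCourse],
    candidates: Optional[Sequence[tuple[int, int]]] = None,
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 500,
) -> JLCMResults:
    """Fit every candidate ``(n_classes, poly_order)`` and return the lowest
    BIC, ties broken toward fewer classes then lower order.

    Default grid: classes 1-3 x polynomial order 1-3.
    """
    import pandas as pd
    if candidates is None:
        candidates = [(G, p) for G in (1, 2, 3) for p in (1, 2, 3)]
    candidates = sorted(candidates)  # tie-break order: smaller G, then p
    best, rows = None, []
    for G, p in candidates:
        spec = ModelSpec(n_classes=G, poly_order=p)
        try:
            res = JointLatentClassModel(courses, spec).fit(
                n_starts=n_starts, seed=seed, maxiter=maxiter
            )
        except FitError:
            rows.append((G, p, np.nan, np.nan, False))
            continue
        rows.append((G, p, res.loglik, res.bic, res.converged))
        if best is None:
            best = res
        elif res.converged and not best.converged:
            best = res
        elif res.converged == best.converged and res.bic < best.bic - 1e-9:
            best = res
    if best is None:
        raise FitError("all candidate fits failed")
    best.selection_table = pd.DataFrame(
        rows, columns=["n_classes", "poly_order", "loglik", "bic", "converged"]
    )
    return best
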