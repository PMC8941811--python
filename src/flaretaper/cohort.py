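"""Patient-course containers, course assembly and eligibility filtering.

A *course* is one uninterrupted period of treatment with a given biologic
DMARD.  The analysis clock of a course starts ("baseline") at the first visit
with DAS28 <= 3.2 (low disease activity, LDA) recorded after at least 24
weeks of treatment; everything upstream of that anchor is eligibility
history, everything downstream is follow-up during which tapering and flares
are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .das28 import Das28Components, detect_flare

__all__ = [
    "VisitRecord",
    "CourseCovariates",
    "PatientCourse",
    "IneligibleCourseError",
    "assemble_course",
    "filter_eligible",
    "read_cohort",
    "write_cohort",
    "LDA_THRESHOLD",
    "MIN_TREATMENT_WEEKS",
    "SURVIVAL_COVARIATES",
]

#: low disease activity threshold on the DAS28 scale
LDA_THRESHOLD = 3.2
#: minimum weeks of treatment before the LDA anchor may be set
MIN_TREATMENT_WEEKS = 24.0

#: fixed covariates entering the survival submodel, in reporting order
SURVIVAL_COVARIATES = (
    "time_to_lda_weeks",
    "das28_baseline",
    "dose_fraction_baseline",
    "sj_increase_baseline",
    "tj_increase_baseline",
    "disease_duration_years",
    "seropositive",
    "tnfi",
)


class IneligibleCourseError(ValueError):
    """The course has no qualifying LDA visit (or fails eligibility)."""


@dataclass(frozen=True)
class VisitRecord:
    """One clinic visit: time (weeks from baseline), DAS28, dose, flare flag."""

    time: float
    das28: Optional[float] = None
    components: Optional[Das28Components] = None
    dose_fraction: float = 1.0
    flare: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dose_fraction <= 1.0:
            raise ValueError(f"dose_fraction out of [0,1]: {self.dose_fraction}")
        if self.das28 is not None and self.das28 < 0:
            raise ValueError(f"das28 negative: {self.das28}")


@dataclass(frozen=True)
class CourseCovariates:
    """Fixed per-course covariates of the flare-hazard submodel.

    The model requires complete cases: every field must be present.
    """

    seropositive: bool
    disease_duration_years: float
    time_to_lda_weeks: float
    das28_baseline: float
    dose_fraction_baseline: float
    tj_increase_baseline: bool
    sj_increase_baseline: bool
    tnfi: bool

    def as_vector(self) -> np.ndarray:
        """Covariates in :data:`SURVIVAL_COVARIATES` order."""
        return np.array([float(getattr(self, k)) for k in SURVIVAL_COVARIATES])


@dataclass
class PatientCourse:
    """A bDMARD course re-anchored at its LDA baseline."""

    course_id: str
    patient_id: str
    visits: list[VisitRecord]
    covariates: CourseCovariates
    first_flare_time: Optional[float] = None
    censor_time: float = 0.0
    #: ground-truth latent class, populated by the synthetic generator only
    true_class: Optional[int] = None
    #: all flare times (weeks), including recurrences beyond the first
    flare_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [v.time for v in self.visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("visit times must be strictly increasing")
        if self.first_flare_time is not None and self.first_flare_time > self.censor_time:
            raise ValueError("first_flare_time exceeds censor_time")

    # -- dose step function -------------------------------------------------
    def dose_at(self, t: float | np.ndarray) -> np.ndarray:
        """Dose fraction in force at time ``t`` (piecewise constant; the dose
        recorded at a visit holds from that visit until the next)."""
        times = np.array([v.time for v in self.visits])
        doses = np.array([v.dose_fraction for v in self.visits])
        idx = np.clip(np.searchsorted(times, np.atleast_1d(t), side="right") - 1, 0, None)
        out = doses[idx]
        return out if np.ndim(t) else float(out[0])

    def dose_change_times(self) -> np.ndarray:
        """Times at which the recorded dose changes (excluding baseline)."""
        times, doses = [], []
        for v in self.visits:
            if not doses or v.dose_fraction != doses[-1]:
                times.append(v.time)
                doses.append(v.dose_fraction)
        return np.array(times[1:])

    @property
    def event_time(self) -> float:
        """Time to first flare, or censoring time if no flare."""
        return self.first_flare_time if self.first_flare_time is not None else self.censor_time

    @property
    def event_observed(self) -> bool:
        return self.first_flare_time is not None

    def observations(self, up_to: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
        """(times, DAS28 values) of visits with a DAS28, optionally <= ``up_to``."""
        t = [v.time for v in self.visits if v.das28 is not None]
        y = [v.das28 for v in self.visits if v.das28 is not None]
        t, y = np.array(t, dtype=float), np.array(y, dtype=float)
        if up_to is not None:
            keep = t <= up_to
            t, y = t[keep], y[keep]
        return t, y


def assemble_course(
    course_id: str,
    patient_id: str,
    visits: Sequence[VisitRecord],
    covariates: CourseCovariates,
    min_treatment_weeks: float = MIN_TREATMENT_WEEKS,
    derive_flares: bool = True,
) -> PatientCourse:
    """Re-anchor a visit series at its LDA baseline and derive flare flags.

    ``visits`` carry times on the treatment clock (weeks from bDMARD start).
    The first visit with DAS28 <= 3.2 at or after ``min_treatment_weeks``
    becomes time 0; earlier visits are dropped.  Flare flags are derived from
    consecutive visit pairs via the DAS28/dose-increase criterion unless
    ``derive_flares`` is False, in which case the flags supplied on the input
    visits are trusted (e.g., synthetic ground truth or pre-flagged data).

    Raises
    ------
    IneligibleCourseError
        If no qualifying LDA visit exists.
    """
    visits = sorted(visits, key=lambda v: v.time)
    anchor = None
    for v in visits:
        if v.das28 is not None and v.das28 <= LDA_THRESHOLD and v.time >= min_treatment_weeks:
            anchor = v.time
            break
    if anchor is None:
        raise IneligibleCourseError(
            f"course {course_id}: no DAS28 <= {LDA_THRESHOLD} at >= {min_treatment_weeks} weeks"
        )
    kept = [replace(v, time=v.time - anchor) for v in visits if v.time >= anchor]

    if derive_flares:
        flagged = [replace(kept[0], flare=False)]
        for prev, curr in zip(kept, kept[1:]):
            flagged.append(
                replace(
                    curr,
                    flare=detect_flare(prev.das28, curr.das28, prev.dose_fraction, curr.dose_fraction),
                )
            )
        kept = flagged

    flare_times = [v.time for v in kept if v.flare and v.time > 0]
    first_flare = flare_times[0] if flare_times else None
    censor = kept[-1].time
    return PatientCourse(
        course_id=course_id,
        patient_id=patient_id,
        visits=kept,
        covariates=covariates,
        first_flare_time=first_flare,
        censor_time=max(censor, first_flare or 0.0),
        flare_times=flare_times,
    )


def filter_eligible(
    courses: Iterable[PatientCourse],
    min_rate_per_year: float = 2.0,
) -> tuple[list[PatientCourse], list[tuple[str, str]]]:
    """Keep courses with complete covariates and >= 2 DAS28 measurements/year.

    Returns ``(kept, dropped)`` where ``dropped`` lists ``(course_id, reason)``.
    """
    kept, dropped = [], []
    for c in courses:
        vec = c.covariates.as_vector()
        if not np.all(np.isfinite(vec)):
            dropped.append((c.course_id, "incomplete covariates"))
            continue
        t, _ = c.observations()
        followup_years = max(c.censor_time, 1e-9) / 52.0
        if len(t) / followup_years < min_rate_per_year:
            dropped.append((c.course_id, "DAS28 measurement rate < 2/year"))
            continue
        kept.append(c)
    return kept, dropped


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_VISIT_COLS = ["course_id", "patient_id", "week", "tjc28", "sjc28", "esr", "crp",
               "gh", "das28", "dose_fraction", "flare"]
_COV_COLS = ["course_id", "patient_id", *SURVIVAL_COVARIATES]


def write_cohort(courses: Sequence[PatientCourse], visits_path, covariates_path) -> None:
    """Write a cohort as a visit-level CSV plus a per-course covariate CSV."""
    vrows, crows = [], []
    for c in courses:
        for v in c.visits:
            comp = v.components
            vrows.append({
                "course_id": c.course_id, "patient_id": c.patient_id, "week": v.time,
                "tjc28": comp.tjc28 if comp else None,
                "sjc28": comp.sjc28 if comp else None,
                "esr": comp.esr if comp else None,
                "crp": comp.crp if comp else None,
                "gh": comp.gh if comp else None,
                "das28": v.das28, "dose_fraction": v.dose_fraction,
                "flare": int(v.flare),
            })
        row = {"course_id": c.course_id, "patient_id": c.patient_id}
        for k in SURVIVAL_COVARIATES:
            val = getattr(c.covariates, k)
            row[k] = int(val) if isinstance(val, bool) else val
        crows.append(row)
    pd.DataFrame(vrows, columns=_VISIT_COLS).to_csv(visits_path, index=False)
    pd.DataFrame(crows, columns=_COV_COLS).to_csv(covariates_path, index=False)


def read_cohort(visits_path, covariates_path) -> list[PatientCourse]:
    """Read a cohort written by :func:`write_cohort`.

    Times in the files are already on the baseline-anchored clock; flare
    flags are taken from the file (round-trip preserving).
    """
    vdf = pd.read_csv(visits_path)
    cdf = pd.read_csv(covariates_path).set_index("course_id")
    courses = []
    for cid, grp in vdf.groupby("course_id", sort=False):
        grp = grp.sort_values("week")
        visits = []
        for _, r in grp.iterrows():
            comp = None
            if pd.notna(r.get("tjc28")) and pd.notna(r.get("sjc28")):
                comp = Das28Components(
                    tjc28=int(r["tjc28"]), sjc28=int(r["sjc28"]),
                    esr=None if pd.isna(r["esr"]) else float(r["esr"]),
                    crp=None if pd.isna(r["crp"]) else float(r["crp"]),
                    gh=None if pd.isna(r["gh"]) else float(r["gh"]),
                    time=float(r["week"]),
                )
            visits.append(VisitRecord(
                time=float(r["week"]),
                das28=None if pd.isna(r["das28"]) else float(r["das28"]),
                components=comp,
                dose_fraction=float(r["dose_fraction"]),
                flare=bool(int(r["flare"])) if pd.notna(r["flare"]) else False,
            ))
        cov_row = cdf.loc[cid]
        cov = CourseCovariates(
            seropositive=bool(int(cov_row["seropositive"])),
            disease_duration_years=float(cov_row["disease_duration_years"]),
            time_to_lda_weeks=float(cov_row["time_to_lda_weeks"]),
            das28_baseline=float(cov_row["das28_baseline"]),
            dose_fraction_baseline=float(cov_row["dose_fraction_baseline"]),
            tj_increase_baseline=bool(int(cov_row["tj_increase_baseline"])),
            sj_increase_baseline=bool(int(cov_row["sj_increase_baseline"])),
            tnfi=bool(int(cov_row["tnfi"])),
        )
        flare_times = [v.time for v in visits if v.flare and v.time > 0]
        first_flare = flare_times[0] if flare_times else None
        courses.append(PatientCourse(
            course_id=str(cid), patient_id=str(cov_row["patient_id"]),
            visits=visits, covariates=cov,
            first_flare_time=first_flare,
            censor_time=max(visits[-1].time, first_flare or 0.0),
            flare_times=flare_times,
        ))
    return courses
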