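"""DAS28 compositing and the flare criterion.

The Disease Activity Score over 28 joints (DAS28) combines tender and swollen
joint counts, an inflammation marker (ESR in mm/h or CRP in mg/L) and,
optionally, the patient's global-health VAS (0-100 mm).  Four validated
formulae exist (ESR/CRP x 3-/4-variable); routine-care records rarely contain
every component at every visit, so the composite used throughout this package
is the mean of all formulae computable from the components at hand.

A flare is a clinically relevant worsening of disease activity: a DAS28
increase > 1.2 since the previous visit, or an increase > 0.6 reaching
DAS28 > 3.2.  Because a clinician reacting to worsening may raise the biologic
dose before a DAS28 is recorded, any increase in bDMARD dose also counts as a
flare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "Das28Components",
    "InsufficientComponentsError",
    "compute_das28_variants",
    "compose_das28",
    "match_components",
    "detect_flare",
    "COMPONENT_WINDOW_WEEKS",
]

#: half-width of the window within which lab/exam components may be matched
#: to a visit (4 weeks = 28 days).
COMPONENT_WINDOW_WEEKS = 4.0


class InsufficientComponentsError(ValueError):
    """No DAS28 variant is computable from the available components."""


@dataclass(frozen=True)
class Das28Components:
    """Component measurements feeding the DAS28 at one visit.

    ``esr``, ``crp`` and ``gh`` may be ``None`` (absent); at least one of
    ESR/CRP must be present for any score to be computable.
    """

    tjc28: int
    sjc28: int
    esr: Optional[float] = None  # mm/hour
    crp: Optional[float] = None  # mg/L
    gh: Optional[float] = None  # VAS 0-100 mm
    time: float = 0.0  # weeks from course baseline

    def __post_init__(self) -> None:
        if not 0 <= self.tjc28 <= 28:
            raise ValueError(f"tjc28 out of range: {self.tjc28}")
        if not 0 <= self.sjc28 <= 28:
            raise ValueError(f"sjc28 out of range: {self.sjc28}")
        if self.gh is not None and not 0 <= self.gh <= 100:
            raise ValueError(f"gh out of range: {self.gh}")
        if self.crp is not None and self.crp < 0:
            raise ValueError(f"crp negative: {self.crp}")
        if self.esr is not None and self.esr < 0:
            raise ValueError(f"esr negative: {self.esr}")


def _joint_part(c: Das28Components) -> float:
    return 0.56 * math.sqrt(c.tjc28) + 0.28 * math.sqrt(c.sjc28)


def compute_das28_variants(c: Das28Components) -> list[tuple[str, float]]:
    """All DAS28 variants computable from the present components.

    Returns ``(name, score)`` pairs for each of ``esr4``, ``esr3``, ``crp4``,
    ``crp3`` whose inputs are present.  ESR is floored at 1 mm/h before the
    logarithm so a recorded ESR of 0 yields a finite score.

    Raises
    ------
    InsufficientComponentsError
        If neither ESR nor CRP is present.
    """
    variants: list[tuple[str, float]] = []
    jp = _joint_part(c)
    if c.esr is not None:
        esr_term = 0.70 * math.log(max(c.esr, 1.0))
        if c.gh is not None:
            variants.append(("esr4", jp + esr_term + 0.014 * c.gh))
        variants.append(("esr3", (jp + esr_term) * 1.08 + 0.16))
    if c.crp is not None:
        crp_term = 0.36 * math.log(c.crp + 1.0)
        if c.gh is not None:
            variants.append(("crp4", jp + crp_term + 0.014 * c.gh + 0.96))
        variants.append(("crp3", (jp + crp_term) * 1.10 + 1.10))
    if not variants:
        raise InsufficientComponentsError(
            "insufficient components: need ESR or CRP for any DAS28 variant"
        )
    return variants


def compose_das28(c: Das28Components) -> float:
    """Arithmetic mean of all computable DAS28 variants."""
    variants = compute_das28_variants(c)
    return sum(score for _, score in variants) / len(variants)


def match_components(
    measurements: Mapping[str, Sequence[tuple[float, float]]],
    visit_time: float,
    tjc28: int,
    sjc28: int,
    window: float = COMPONENT_WINDOW_WEEKS,
) -> Das28Components:
    """Match time-stamped lab/VAS measurements to a visit.

    ``measurements`` maps component names (``"esr"``, ``"crp"``, ``"gh"``) to
    sequences of ``(time_weeks, value)`` pairs on the same clock as
    ``visit_time``.  For each component the measurement nearest the visit and
    within ``window`` weeks is selected; ties in distance are broken toward
    the earlier measurement.  Components without a match are absent.
    """
    chosen: dict[str, Optional[float]] = {}
    for name in ("esr", "crp", "gh"):
        best: Optional[tuple[float, float, float]] = None  # (|dt|, t, value)
        for t, value in measurements.get(name, ()):
            dt = abs(t - visit_time)
            if dt > window:
                continue
            if best is None or dt < best[0] or (dt == best[0] and t < best[1]):
                best = (dt, t, value)
        chosen[name] = None if best is None else best[2]
    return Das28Components(
        tjc28=tjc28, sjc28=sjc28, time=visit_time,
        esr=chosen["esr"], crp=chosen["crp"], gh=chosen["gh"],
    )


def detect_flare(
    prev_das28: Optional[float],
    curr_das28: Optional[float],
    prev_dose: float,
    curr_dose: float,
) -> bool:
    """Flare criterion between two consecutive visits.

    True iff the DAS28 rose by more than 1.2, rose by more than 0.6 to a
    value above 3.2, or the bDMARD dose was increased.  The DAS28 clauses are
    skipped when either score is absent (``None``).
    """
    if curr_dose > prev_dose:
        return True
    if prev_das28 is None or curr_das28 is None:
        return False
    delta = curr_das28 - prev_das28
    if delta > 1.2:
        return True
    if delta > 0.6 and curr_das28 > 3.2:
        return True
    return False
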