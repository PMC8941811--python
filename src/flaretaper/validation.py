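"""Predictive-performance assessment of landmark flare predictions.

Discrimination is the pooled AUC-ROC over all landmark predictions
(Mann-Whitney form, ties counted 1/2); the operating cutoff is chosen by
Youden's index (sensitivity + specificity - 1) with classification rule
``risk >= cutoff``; per-cutoff performance gets patient-level bootstrap
percentile confidence intervals; calibration compares mean predicted risk
with observed flare frequency in predicted-risk quartiles.
Out-of-sample predictions come from k-fold cross-validation with folds split
by *patient* (all courses of one patient share a fold), stratified by
whether the patient ever flared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import PatientCourse
from .jlcm import JointLatentClassModel, ModelSpec
from .prediction import FLARE, INDETERMINATE, RiskPrediction, landmark_predictions

__all__ = [
    "PerformanceTable",
    "CalibrationGroups",
    "crossvalidate",
    "auc_roc",
    "youden_cutoff",
    "performance_at_cutoff",
    "calibration",
    "patient_folds",
]


def _labeled(preds: Sequence[RiskPrediction]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(risks, binary labels, patient ids) of determinate predictions."""
    kept = [p for p in preds if p.label != INDETERMINATE]
    risks = np.array([p.risk for p in kept])
    y = np.array([1 if p.label == FLARE else 0 for p in kept])
    pid = np.array([p.patient_id for p in kept])
    return risks, y, pid


def auc_roc(preds: Sequence[RiskPrediction]) -> float:
    """Pooled AUC-ROC over all determinate predictions.

    Probability that a randomly chosen flare-labelled prediction carries a
    higher risk than a randomly chosen no-flare one, ties counted 1/2.
    """
    risks, y, _ = _labeled(preds)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("undefined AUC: both labels required")
    ranks = rankdata(risks)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_cutoff(preds: Sequence[RiskPrediction]) -> float:
    """Observed risk value maximising sensitivity + specificity - 1 for the
    rule ``risk >= cutoff``; ties broken toward the lower cutoff."""
    risks, y, _ = _labeled(preds)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both labels required for a cutoff")
    candidates = np.unique(risks)
    best_c, best_j = candidates[0], -np.inf
    n1, n0 = y.sum(), (1 - y).sum()
    for c in candidates:
        pos = risks >= c
        j = (pos & (y == 1)).sum() / n1 + ((~pos) & (y == 0)).sum() / n0 - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


@dataclass
class PerformanceTable:
    """Discrimination/classification metrics with 95% bootstrap CIs.

    ``ppv`` may be ``nan`` (flagged by ``ppv_defined = False``) when no
    prediction exceeds the cutoff.
    """

    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    ci: dict[str, tuple[float, float]]
    ppv_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            rows.append((name, getattr(self, name), lo, hi))
        return pd.DataFrame(rows, columns=["metric", "estimate", "ci_lower", "ci_upper"])

    def __str__(self) -> str:
        head = f"Performance at cutoff {self.cutoff:.3f}\n"
        return head + self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3f}")


def _point_metrics(risks: np.ndarray, y: np.ndarray, cutoff: float) -> dict[str, float]:
    pos = risks >= cutoff
    tp = int((pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    fn = int((~pos & (y == 1)).sum())
    tn = int((~pos & (y == 0)).sum())
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "accuracy": (tp + tn) / len(y) if len(y) else np.nan,
    }
    # AUC on the bootstrap sample may be undefined for single-class resamples
    n1, n0 = y.sum(), (1 - y).sum()
    if n1 and n0:
        ranks = rankdata(risks)
        out["auc"] = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    else:
        out["auc"] = np.nan
    return out


def performance_at_cutoff(
    preds: Sequence[RiskPrediction],
    cutoff: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> PerformanceTable:
    """Classification metrics at ``risk >= cutoff`` with patient-level
    nonparametric bootstrap percentile 95% CIs (B = ``n_boot``)."""
    risks, y, pid = _labeled(preds)
    point = _point_metrics(risks, y, cutoff)
    patients = np.unique(pid)
    groups = {p: np.flatnonzero(pid == p) for p in patients}
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        take = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([groups[p] for p in take])
        m = _point_metrics(risks[idx], y[idx], cutoff)
        for k, v in m.items():
            if np.isfinite(v):
                samples[k].append(v)
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        if v else (np.nan, np.nan)
        for k, v in samples.items()
    }
    return PerformanceTable(
        cutoff=cutoff, auc=point["auc"],
        sensitivity=point["sensitivity"], specificity=point["specificity"],
        ppv=point["ppv"], npv=point["npv"], accuracy=point["accuracy"],
        ci=ci, ppv_defined=bool(np.isfinite(point["ppv"])),
    )


@dataclass
class CalibrationGroups:
    """Quartile calibration of predicted risk vs observed flare frequency."""

    bounds: np.ndarray          # 25th/50th/75th percentiles of predicted risk
    mean_predicted: np.ndarray  # per group
    observed_frequency: np.ndarray
    n: np.ndarray
    degenerate: bool = False    # all predictions identical -> single group

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": np.arange(1, len(self.n) + 1),
            "mean_predicted": self.mean_predicted,
            "observed_frequency": self.observed_frequency,
            "n": self.n,
        })


def calibration(preds: Sequence[RiskPrediction]) -> CalibrationGroups:
    """Group determinate predictions by predicted-risk quartiles and compare
    mean predicted risk with the observed flare frequency per group."""
    risks, y, _ = _labeled(preds)
    if len(risks) < 4:
        raise ValueError("need at least 4 determinate predictions")
    bounds = np.percentile(risks, [25, 50, 75])
    if np.allclose(risks, risks[0]):
        return CalibrationGroups(
            bounds=bounds,
            mean_predicted=np.array([risks.mean()]),
            observed_frequency=np.array([y.mean()]),
            n=np.array([len(y)]),
            degenerate=True,
        )
    group = np.searchsorted(bounds, risks, side="right")
    mp, of, ns = [], [], []
    for g in range(4):
        m = group == g
        if not m.any():
            continue
        mp.append(risks[m].mean())
        of.append(y[m].mean())
        ns.append(int(m.sum()))
    return CalibrationGroups(
        bounds=bounds, mean_predicted=np.array(mp),
        observed_frequency=np.array(of), n=np.array(ns),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def patient_folds(
    courses: Sequence[PatientCourse], k: int, seed: int
) -> list[list[int]]:
    """Seeded k-fold partition of course indices split by patient and
    stratified by whether the patient ever flared."""
    by_patient: dict[str, list[int]] = {}
    for i, c in enumerate(courses):
        by_patient.setdefault(c.patient_id, []).append(i)
    patients = sorted(by_patient)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    flared = {p: any(courses[i].event_observed for i in by_patient[p]) for p in patients}
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for stratum in (True, False):
        grp = [p for p in patients if flared[p] == stratum]
        rng.shuffle(grp)
        for j, p in enumerate(grp):
            folds[j % k].extend(by_patient[p])
    return folds


def crossvalidate(
    courses: Sequence[PatientCourse],
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    n_starts: int = 4,
    maxiter: int = 500,
    include_baseline: bool = True,
) -> list[RiskPrediction]:
    """Pooled out-of-fold landmark predictions from patient-level k-fold CV.

    For each fold the model is refitted on the remaining folds and the
    held-out fold's visits are predicted.  A fold whose fit fails raises,
    naming the fold.
    """
    folds = patient_folds(courses, k, seed)
    pooled: list[RiskPrediction] = []
    for f, test_idx in enumerate(folds):
        train = [c for i, c in enumerate(courses) if i not in set(test_idx)]
        test = [courses[i] for i in test_idx]
        if not test:
            continue
        try:
            fitted = JointLatentClassModel(train, spec).fit(
                n_starts=n_starts, seed=seed + 1000 * (f + 1), maxiter=maxiter
            )
        except Exception as exc:  # noqa: BLE001 - annotate with fold id
            raise RuntimeError(f"cross-validation fit failed in fold {f}") from exc
        pooled.extend(landmark_predictions(test, fitted, include_baseline=include_baseline))
    return pooled
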