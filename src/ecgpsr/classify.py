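"""Two-threshold, three-class CV classifier.

Training inspects each subject's CV trace around the known healthy-to-
unhealthy transition: windows up to index ``a`` contain only healthy
beats, windows from index ``b`` onward only unhealthy ones.  Per subject
i the extrema

    Th_max_i = max CV over the healthy prefix [0 .. a]
    Th_min_i = min CV over the unhealthy suffix [b .. end]

are pooled across subjects into the final pair

    Th_final_max = max_i Th_max_i        (upper edge of the healthy band)
    Th_final_min = min_i Th_min_i        (lower edge of the unhealthy band)

and a CV value is classified as

    CV <= Th_final_max                      -> healthy
    CV >= Th_final_min                      -> unhealthy
    Th_final_max < CV < Th_final_min        -> tending_to_unhealthy

The reference thresholds learned on the original 65-subject cohort are
shipped as :data:`PUBLISHED_THRESHOLDS`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trends import CVTrace

__all__ = [
    "LabeledCVTrace",
    "ThresholdPair",
    "ClassDecision",
    "LABELS",
    "PUBLISHED_THRESHOLDS",
    "patient_extrema",
    "learn_thresholds",
    "classify_cv",
    "classify_trace",
    "split_train_validate",
]

logger = logging.getLogger(__name__)

#: decision labels in increasing order of severity
LABELS = ("healthy", "tending_to_unhealthy", "unhealthy")


@dataclass
class ThresholdPair:
    """Learned (Th_final_max, Th_final_min) for one feature kind.

    A usable three-band rule needs th_final_max < th_final_min; pairs
    violating this (possible when cohorts overlap) are flagged
    ``degenerate`` and classification degrades to a two-class rule at
    the midpoint.
    """

    th_final_max: float
    th_final_min: float
    kind: str
    n_patients: int = 0

    def __post_init__(self):
        # th_final_max may be exactly 0 for perfectly regular cohorts
        # (every healthy window identical); the unhealthy-side threshold
        # must be strictly positive
        if self.th_final_max < 0 or self.th_final_min <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def degenerate(self) -> bool:
        return self.th_final_max >= self.th_final_min

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind,
                           "th_final_max": self.th_final_max,
                           "th_final_min": self.th_final_min,
                           "n_patients": self.n_patients})

    @classmethod
    def from_json(cls, text: str) -> "ThresholdPair":
        d = json.loads(text)
        return cls(th_final_max=d["th_final_max"],
                   th_final_min=d["th_final_min"],
                   kind=d["kind"], n_patients=d.get("n_patients", 0))


#: Reference thresholds from the original 65-subject study cohort.
PUBLISHED_THRESHOLDS = {
    "PR": ThresholdPair(th_final_max=0.068, th_final_min=0.1012,
                        kind="PR", n_patients=65),
    "QRS": ThresholdPair(th_final_max=0.069, th_final_min=0.083,
                         kind="QRS", n_patients=65),
    "QT": ThresholdPair(th_final_max=0.079, th_final_min=0.082,
                        kind="QT", n_patients=65),
}


@dataclass
class LabeledCVTrace:
    """A CV trace with its transition landmarks.

    ``a_index`` is the last window whose beats are all healthy and
    ``b_index`` the first whose beats are all unhealthy; windows in
    between straddle the transition.
    """

    trace: CVTrace
    a_index: int
    b_index: int
    patient_id: str = ""

    def __post_init__(self):
        n = len(self.trace)
        if not (0 <= self.a_index < self.b_index <= n - 1):
            raise ValueError(
                f"need 0 <= a_index < b_index <= {n - 1}, got "
                f"({self.a_index}, {self.b_index})")


@dataclass
class ClassDecision:
    label: str
    cv: float
    kind: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")

    @property
    def severity(self) -> int:
        return LABELS.index(self.label)


def patient_extrema(labeled: LabeledCVTrace) -> tuple[float, float]:
    """(Th_max_i, Th_min_i): max CV of the healthy prefix, min CV of the
    unhealthy suffix."""
    cvs = labeled.trace.cvs
    th_max = float(np.max(cvs[: labeled.a_index + 1]))
    th_min = float(np.min(cvs[labeled.b_index:]))
    return th_max, th_min


def learn_thresholds(labeled_set: Sequence[LabeledCVTrace],
                     kind: str) -> ThresholdPair:
    """Pool per-patient extrema: max of maxima, min of minima."""
    labeled_set = list(labeled_set)
    if not labeled_set:
        raise ValueError("empty training set")
    maxima, minima = zip(*(patient_extrema(lt) for lt in labeled_set))
    pair = ThresholdPair(th_final_max=float(max(maxima)),
                         th_final_min=float(min(minima)),
                         kind=kind, n_patients=len(labeled_set))
    if pair.degenerate:
        logger.warning("learn_thresholds(%s): degenerate pair "
                       "(max %.4g >= min %.4g); cohorts overlap",
                       kind, pair.th_final_max, pair.th_final_min)
    return pair


def classify_cv(cv: float, thresholds: ThresholdPair) -> ClassDecision:
    """Apply the three-band rule to one CV value.

    Ties go with the band: ``cv <= th_final_max`` is healthy and
    ``cv >= th_final_min`` is unhealthy (both inclusive).  With a
    degenerate pair the rule degrades to two classes split at the
    midpoint, with a warning.
    """
    if thresholds.degenerate:
        warnings.warn(f"degenerate thresholds for {thresholds.kind}: "
                      "falling back to a two-class midpoint rule")
        mid = 0.5 * (thresholds.th_final_max + thresholds.th_final_min)
        label = "unhealthy" if cv >= mid else "healthy"
        return ClassDecision(label=label, cv=float(cv), kind=thresholds.kind)
    if cv <= thresholds.th_final_max:
        label = "healthy"
    elif cv >= thresholds.th_final_min:
        label = "unhealthy"
    else:
        label = "tending_to_unhealthy"
    return ClassDecision(label=label, cv=float(cv), kind=thresholds.kind)


def classify_trace(trace: CVTrace,
                   thresholds: ThresholdPair
                   ) -> tuple[list[ClassDecision], ClassDecision]:
    """Per-window decisions plus the subject-level decision.

    The subject is unhealthy if any window is, else tending if any
    window is, else healthy (the most severe window label wins).
    """
    if len(trace) == 0:
        raise ValueError("empty CV trace")
    decisions = [classify_cv(cv, thresholds) for cv in trace.cvs]
    worst = max(decisions, key=lambda d: d.severity)
    subject = ClassDecision(label=worst.label, cv=worst.cv, kind=trace.kind)
    return decisions, subject


def split_train_validate(records: Sequence, labels: Sequence[str],
                         train_fraction: float = 0.8,
                         seed: int = 0) -> tuple[list, list]:
    """Seeded stratified split into (train, validation) lists of records.

    The total training size is floor(train_fraction * n); it is
    apportioned to strata by largest remainder so every class is
    represented proportionally.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    records = list(records)
    labels = list(labels)
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    if not records:
        raise ValueError("empty record set")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        strata.setdefault(lab, []).append(i)
    n_train_total = int(np.floor(train_fraction * len(records)))
    # largest-remainder apportionment of the training quota
    quotas = {lab: train_fraction * len(idx) for lab, idx in strata.items()}
    base = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    leftover = n_train_total - sum(base.values())
    order = sorted(strata, key=lambda lab: quotas[lab] - base[lab], reverse=True)
    for lab in order[:leftover]:
        base[lab] += 1
    train_idx: list[int] = []
    val_idx: list[int] = []
    for lab in sorted(strata):
        idx = np.array(strata[lab])
        rng.shuffle(idx)
        k = base[lab]
        train_idx.extend(idx[:k].tolist())
        val_idx.extend(idx[k:].tolist())
    if not train_idx or not val_idx:
        raise ValueError("split leaves train or validation set empty")
    train_idx.sort()
    val_idx.sort()
    return [records[i] for i in train_idx], [records[i] for i in val_idx]
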