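"""Dichotomized prodromal-AD research criteria.

Markers: the RAVLT hippocampal-memory core criterion (delayed recall < 3
AND delayed recognition < 10), visual medial temporal atrophy (Scheltens
>= 3), and CSF positivity (Tau > 93 pg/ml, Abeta1-42 < 192 pg/ml) in OR
and AND composites. Missing modalities are represented tri-state, never
raised as errors; composites over a half-missing CSF pair follow Kleene
three-valued logic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cohort import SubjectRecord


class TriState(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNAVAILABLE = "unavailable"


class Likelihood(enum.Enum):
    HIGH = "high"
    INTERMEDIATE = "intermediate"
    UNINFORMATIVE = "uninformative"
    LOW = "low"
    INDETERMINATE = "indeterminate"


class Prediction(enum.Enum):
    CONVERTER = "predict_converter"
    NONCONVERTER = "predict_nonconverter"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class CriteriaCutoffs:
    """Dichotomization cutoffs; boundary strictness is exactly as stated
    (recall < 3 means 3 is negative, Scheltens >= 3 means 3 is positive,
    Tau > 93 means 93 is negative, Abeta < 192 means 192 is negative)."""

    ravlt_recall_cut: float = 3.0
    ravlt_recognition_cut: float = 10.0
    scheltens_cut: float = 3.0
    tau_cut: float = 93.0
    abeta_cut: float = 192.0
    csf_combination_for_likelihood: str = "or"  # or | and

    def __post_init__(self):
        if self.csf_combination_for_likelihood not in ("or", "and"):
            raise ValueError("csf_combination_for_likelihood must be 'or' or 'and'")


DEFAULT_CUTOFFS = CriteriaCutoffs()


@dataclass(frozen=True)
class MarkerStatus:
    ravlt: TriState
    mta: TriState
    tau: TriState
    abeta: TriState
    csf_or: TriState
    csf_and: TriState

    @property
    def ravlt_positive(self) -> bool:
        return self.ravlt is TriState.POSITIVE


def kleene_or(a: TriState, b: TriState) -> TriState:
    if TriState.POSITIVE in (a, b):
        return TriState.POSITIVE
    if a is TriState.NEGATIVE and b is TriState.NEGATIVE:
        return TriState.NEGATIVE
    return TriState.UNAVAILABLE


def kleene_and(a: TriState, b: TriState) -> TriState:
    if TriState.NEGATIVE in (a, b):
        return TriState.NEGATIVE
    if a is TriState.POSITIVE and b is TriState.POSITIVE:
        return TriState.POSITIVE
    return TriState.UNAVAILABLE


def _value(features: Mapping[str, float | None], name: str) -> float | None:
    v = features.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def dichotomize(
    subject: SubjectRecord | Mapping[str, float | None],
    cutoffs: CriteriaCutoffs = DEFAULT_CUTOFFS,
) -> MarkerStatus:
    """Map one subject's measurements to tri-state marker positivity."""
    features = subject.features if isinstance(subject, SubjectRecord) else subject

    recall = _value(features, "ravlt_recall")
    recog = _value(features, "ravlt_recognition")
    if recall is None or recog is None:
        ravlt = TriState.UNAVAILABLE
    elif recall < cutoffs.ravlt_recall_cut and recog < cutoffs.ravlt_recognition_cut:
        ravlt = TriState.POSITIVE
    else:
        ravlt = TriState.NEGATIVE

    scheltens = _value(features, "scheltens")
    if scheltens is None:
        mta = TriState.UNAVAILABLE
    else:
        mta = TriState.POSITIVE if scheltens >= cutoffs.scheltens_cut else TriState.NEGATIVE

    tau_v = _value(features, "csf_tau")
    if tau_v is None:
        tau = TriState.UNAVAILABLE
    else:
        tau = TriState.POSITIVE if tau_v > cutoffs.tau_cut else TriState.NEGATIVE

    abeta_v = _value(features, "csf_abeta42")
    if abeta_v is None:
        abeta = TriState.UNAVAILABLE
    else:
        abeta = TriState.POSITIVE if abeta_v < cutoffs.abeta_cut else TriState.NEGATIVE

    return MarkerStatus(
        ravlt=ravlt,
        mta=mta,
        tau=tau,
        abeta=abeta,
        csf_or=kleene_or(tau, abeta),
        csf_and=kleene_and(tau, abeta),
    )


def assign_likelihood(status: MarkerStatus, csf_combination: str = "or") -> Likelihood:
    """Four-way likelihood-of-conversion category (plus indeterminate).

    high:          RAVLT+, MTA+, CSF+
    intermediate:  RAVLT+, one of {MTA, CSF} positive, the other unavailable
    uninformative: RAVLT+, one positive, the other negative
    low:           RAVLT-, MTA-, CSF- (both modalities measured)
    indeterminate: every other pattern
    """
    csf = status.csf_or if csf_combination == "or" else status.csf_and
    mta = status.mta
    P, N, U = TriState.POSITIVE, TriState.NEGATIVE, TriState.UNAVAILABLE
    if status.ravlt is U:
        return Likelihood.INDETERMINATE
    if status.ravlt is P:
        if mta is P and csf is P:
            return Likelihood.HIGH
        if (mta is P and csf is U) or (csf is P and mta is U):
            return Likelihood.INTERMEDIATE
        if (mta is P and csf is N) or (csf is P and mta is N):
            return Likelihood.UNINFORMATIVE
        return Likelihood.INDETERMINATE
    if mta is N and csf is N:
        return Likelihood.LOW
    return Likelihood.INDETERMINATE


#: rule id -> marker fields that must all be positive
RULES: dict[str, tuple[str, ...]] = {
    "r1": ("ravlt",),
    "r2": ("mta",),
    "r3a": ("csf_or",),
    "r3b": ("csf_and",),
    "r1_2": ("ravlt", "mta"),
    "r1_3a": ("ravlt", "csf_or"),
    "r1_2_3a": ("ravlt", "mta", "csf_or"),
    "r1_2_3b": ("ravlt", "mta", "csf_and"),
}


def predict_rule(status: MarkerStatus, rule_id: str) -> Prediction:
    """Binary conversion prediction for one criteria combination.

    Converter iff every marker named by the rule is positive; not
    evaluable iff any named marker is unavailable.
    """
    try:
        markers = RULES[rule_id]
    except KeyError:
        raise ValueError(f"unknown rule_id {rule_id!r}") from None
    states = [getattr(status, m) for m in markers]
    if any(s is TriState.UNAVAILABLE for s in states):
        return Prediction.NOT_EVALUABLE
    if all(s is TriState.POSITIVE for s in states):
        return Prediction.CONVERTER
    return Prediction.NONCONVERTER


def evaluable_subset(
    cohort: Iterable[SubjectRecord],
    rule_id: str,
    cutoffs: CriteriaCutoffs = DEFAULT_CUTOFFS,
) -> list[SubjectRecord]:
    """Subjects for whom the rule's markers are all available."""
    return [
        r
        for r in cohort
        if predict_rule(dichotomize(r, cutoffs), rule_id) is not Prediction.NOT_EVALUABLE
    ]
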