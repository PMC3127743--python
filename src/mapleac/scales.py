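"""Embedded subscales consumed by the MAPLe-AC decision tree.

Implements the Cognitive Performance Scale (CPS, 0-6), the ADL hierarchy
(0-6, from the four late-loss activities: personal hygiene, toilet use,
locomotion, eating), cross-timepoint ADL decline, the four-item behavior
disturbance composite, the 8-category institutional (nursing-home) risk
screener with its >=3 activation cut-off, and the geriatric screener
subscore (the home-care stamina item has no acute-care counterpart and is
structurally absent).

All operations are pure.  Scale-critical missing items raise
:class:`NonComputable` rather than defaulting; boolean clinical/risk flags
missing are treated as "not present" with a logged warning, mirroring how
unchecked boxes behave on interRAI forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .interrai import (
    ADL_DID_NOT_OCCUR,
    ADL_ITEMS,
    BEHAVIOR_ITEMS,
    MISSING,
    Assessment,
    Timepoint,
)

logger = logging.getLogger(__name__)

#: number of institutional-risk categories and the activation cut-off.
N_RISK_CATEGORIES = 8
RISK_ACTIVATION_THRESHOLD = 3

#: screener inputs: five IADL-capacity flags plus the short-term-memory flag.
SCREENER_FLAG_ITEMS = (
    "meal_preparation_problem",
    "medication_management_problem",
    "phone_use_problem",
    "housework_problem",
    "finance_management_problem",
)


class NonComputable(ValueError):
    """A scale cannot be computed: a scale-critical input is missing."""

    def __init__(self, classifier: str, missing: Sequence[str]):
        self.classifier = classifier
        self.missing = list(missing)
        super().__init__(f"{classifier} non-computable; missing items: {self.missing}")


@dataclass(frozen=True)
class InstitutionalRisk:
    """Count of active nursing-home-risk categories (of exactly 8)."""

    count: int
    active: bool

    def __post_init__(self):
        if not (0 <= self.count <= N_RISK_CATEGORIES):
            raise ValueError(f"risk count out of range: {self.count}")
        if self.active != (self.count >= RISK_ACTIVATION_THRESHOLD):
            raise ValueError("active flag inconsistent with count")


def _require(a: Assessment, classifier: str, codes: Sequence[str]) -> list:
    vals = [a.get(c) for c in codes]
    missing = [c for c, v in zip(codes, vals) if v is MISSING]
    if missing:
        raise NonComputable(classifier, missing)
    return vals


def _flag(a: Assessment, code: str) -> bool:
    """Boolean flag with the default-to-absent policy for missing values."""
    v = a.get(code)
    if v is MISSING:
        logger.warning("item %s missing; treated as not present", code)
        return False
    return bool(v)


def _adl_recode(value: int, did_not_occur_as: int = 6) -> int:
    """Collapse the 0-6 (+8) self-performance code to the 0-4 scoring bands.

    0-1 -> 0 (independent / setup help), 2 -> 1 (supervision),
    3 -> 2 (limited assistance), 4-5 -> 3 (extensive/maximal assistance),
    6 -> 4 (total dependence).  The "activity did not occur" code maps to
    ``did_not_occur_as`` (total dependence by convention) first.
    """
    if value == ADL_DID_NOT_OCCUR:
        value = did_not_occur_as
    if value <= 1:
        return 0
    if value == 2:
        return 1
    if value == 3:
        return 2
    if value <= 5:
        return 3
    return 4


def cps_score(a: Assessment, *, did_not_occur_as: int = 6) -> int:
    """Cognitive Performance Scale, 0 (intact) .. 6 (very severe impairment).

    Comatose dominates everything (CPS 6).  Severely impaired decision
    making scores 5, or 6 when combined with total dependence in eating.
    Otherwise the score follows the impairment count (short-term memory
    problem, any decision-making impairment, any problem making self
    understood) refined by the severe-impairment count (decision making
    moderately+ impaired, self-understood sometimes-or-worse).
    """
    comatose, memory, dm, msu = _require(
        a, "cps", ("comatose", "short_term_memory_problem", "decision_making", "making_self_understood")
    )
    if comatose:
        return 6
    if dm == 3:
        eating = a.get("adl_eating")
        if eating is MISSING:
            raise NonComputable("cps", ["adl_eating"])
        if eating == ADL_DID_NOT_OCCUR:
            eating = did_not_occur_as
        return 6 if eating >= 6 else 5
    impair = int(memory == 1) + int(dm >= 1) + int(msu >= 1)
    if impair == 0:
        return 0
    if impair == 1:
        return 1
    severe = int(dm >= 2) + int(msu >= 2)
    return 2 + severe


def adl_hierarchy(a: Assessment, *, did_not_occur_as: int = 6) -> int:
    """ADL hierarchy, 0 (independent) .. 6 (total dependence).

    Late-loss activities are weighted hierarchically: total dependence in
    all four scores 6; total dependence in both eating and locomotion
    scores 5; extensive assistance in eating or locomotion scores 4; in
    hygiene or toilet use, 3; otherwise the worst recoded band (limited
    assistance 2, supervision 1, independent 0).
    """
    raw = _require(a, "adl_hierarchy", ADL_ITEMS)
    hyg, toi, loc, eat = (_adl_recode(v, did_not_occur_as) for v in raw)
    if hyg == toi == loc == eat == 4:
        return 6
    if eat == 4 and loc == 4:
        return 5
    if eat >= 3 or loc >= 3:
        return 4
    if hyg >= 3 or toi >= 3:
        return 3
    worst = max(hyg, toi, loc, eat)
    return worst if worst <= 2 else 2


def adl_decline(premorbid: Assessment, admission: Assessment) -> bool:
    """True iff functional dependence worsened relative to pre-morbid status."""
    return adl_hierarchy(admission) > adl_hierarchy(premorbid)


def behavior_disturbance(a: Assessment) -> bool:
    """Any of: verbally abusive, physically abusive, socially inappropriate,
    resists care (missing flags count as not present)."""
    return any(_flag(a, c) for c in BEHAVIOR_ITEMS)


def institutional_risk_from_categories(categories: Sequence[bool]) -> InstitutionalRisk:
    """Score the 8-category risk sum directly; activation at >= 3 categories."""
    if len(categories) != N_RISK_CATEGORIES:
        raise ValueError(f"expected exactly {N_RISK_CATEGORIES} categories")
    count = sum(bool(c) for c in categories)
    return InstitutionalRisk(count=count, active=count >= RISK_ACTIVATION_THRESHOLD)


def risk_categories(
    a: Assessment, declined: bool, *, homebound_polarity: bool = True
) -> tuple[bool, ...]:
    """The 8 nursing-home-risk categories for one assessment.

    Categories: prior nursing home placement; homebound (does not go out --
    polarity overridable); bladder incontinence; risk diagnosis (any
    dementia, Alzheimer's, multiple sclerosis, head trauma); ADL decline
    relative to pre-morbid status (``declined``, false by definition at the
    pre-morbid point, which has no earlier baseline); hygiene/bathing
    problem; delirium indicator; meal and shopping problem.
    """
    goes_out = a.get("goes_out")
    if goes_out is MISSING:
        logger.warning("item goes_out missing; homebound risk category not scored")
        homebound = False
    else:
        homebound = (not bool(goes_out)) if homebound_polarity else bool(goes_out)
    return (
        _flag(a, "prior_nursing_home"),
        homebound,
        _flag(a, "bladder_incontinence"),
        a.risk_diagnosis,
        declined,
        _flag(a, "hygiene_or_bathing_problem"),
        _flag(a, "delirium_indicator"),
        _flag(a, "meal_shopping_problem"),
    )


def institutional_risk(e, at: Timepoint, **kwargs) -> InstitutionalRisk:
    """Nursing-home risk screener for one episode time point (sum of 8)."""
    a = e.assessment(at)
    if a is None:
        raise NonComputable("inst_risk", [f"assessment:{at.label}"])
    if at is Timepoint.PREMORBID:
        declined = False
    else:
        pre = e.assessment(Timepoint.PREMORBID)
        if pre is None:
            raise NonComputable("inst_risk", ["assessment:premorbid"])
        declined = adl_decline(pre, a)
    return institutional_risk_from_categories(risk_categories(a, declined, **kwargs))


def geriatric_screener(a: Assessment) -> int:
    """Geriatric screener subscore: count of positive screener findings.

    Inputs are the five IADL-capacity flags (meal preparation, medication
    management, telephone use, housework, finances) and the short-term
    memory problem.  A stamina item, part of the home-care screener, has no
    acute-care counterpart and contributes nothing by construction.
    """
    memory = a.get("short_term_memory_problem")
    if memory is MISSING:
        raise NonComputable("screener", ["short_term_memory_problem"])
    return int(bool(memory)) + sum(int(_flag(a, c)) for c in SCREENER_FLAG_ITEMS)
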