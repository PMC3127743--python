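"""The MAPLe-AC decision tree: one episode time point -> one of five levels.

The tree is data, not code: a declarative :class:`TreeSpec` holds an
ordered list of (condition, level) rules evaluated first-match-wins over a
:class:`ClassifierVector`, with a default level making the rule set total.
Conditions are restricted boolean expressions (comparisons, and/or/not,
parentheses) over the vector's field names, validated and compiled at spec
load time; a malformed spec fails at load, never at scoring time.

The shipped default spec is a reference encoding (the published schematic
is not printed as text): LOW when no classifier fires; MILD for isolated
screener or meal-preparation findings; MODERATE for falls, swallowing
difficulty, medication-management problems, decline in decision making, or
mild ADL/CPS impairment; HIGH for ADL >= 3, CPS >= 3, behavior
disturbance, pressure ulcer, or active institutional risk alone;
VERY_HIGH for active institutional risk combined with severe ADL/CPS
impairment or behavior disturbance.  Every rule is overridable from a
config file, and the spec version string travels in all output provenance.
"""

from __future__ import annotations

import ast
import enum
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import yaml

from .interrai import CLASSIFIER_ITEMS, Episode, Timepoint
from .scales import (
    InstitutionalRisk,
    N_RISK_CATEGORIES,
    NonComputable,
    adl_hierarchy,
    behavior_disturbance,
    cps_score,
    geriatric_screener,
)


class PriorityLevel(enum.IntEnum):
    """Five ordered priority levels, low to very high."""

    LOW = 0
    MILD = 1
    MODERATE = 2
    HIGH = 3
    VERY_HIGH = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, s: str) -> "PriorityLevel":
        try:
            return cls[s.upper()]
        except KeyError:
            raise ValueError(f"unknown priority level: {s!r}") from None


@dataclass(frozen=True)
class ClassifierVector:
    """Complete input to the tree; nothing else may influence the level."""

    adl: int
    cps: int
    behavior: bool
    decision_decline: bool
    medication_problem: bool
    pressure_ulcer: bool
    fall: bool
    meal_prep_problem: bool
    swallowing_difficulty: bool
    inst_risk: InstitutionalRisk
    screener: int

    def as_env(self) -> dict:
        """Evaluation environment for rule conditions."""
        return {
            "adl": self.adl,
            "cps": self.cps,
            "behavior": self.behavior,
            "decision_decline": self.decision_decline,
            "medication_problem": self.medication_problem,
            "pressure_ulcer": self.pressure_ulcer,
            "fall": self.fall,
            "meal_prep_problem": self.meal_prep_problem,
            "swallowing_difficulty": self.swallowing_difficulty,
            "inst_risk_count": self.inst_risk.count,
            "inst_risk_active": self.inst_risk.active,
            "screener": self.screener,
        }


#: field names rule conditions may reference.
CONDITION_FIELDS = frozenset(
    {
        "adl",
        "cps",
        "behavior",
        "decision_decline",
        "medication_problem",
        "pressure_ulcer",
        "fall",
        "meal_prep_problem",
        "swallowing_difficulty",
        "inst_risk_count",
        "inst_risk_active",
        "screener",
    }
)

#: vector field -> classifier name in the crosswalk registry.
VECTOR_CLASSIFIERS = (
    "adl_hierarchy",
    "cps",
    "behavior",
    "decision_decline",
    "medication_problem",
    "pressure_ulcer",
    "fall",
    "meal_prep_problem",
    "swallowing_difficulty",
    "inst_risk",
    "screener",
)


class TreeSpecError(ValueError):
    """Malformed tree specification (unknown field, bad expression...)."""


_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Compare,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
)


def _compile_condition(expr: str):
    """Validate and compile a restricted boolean expression over the vector."""
    try:
        node = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise TreeSpecError(f"invalid condition syntax: {expr!r} ({e.msg})") from None
    for sub in ast.walk(node):
        if not isinstance(sub, _ALLOWED_NODES):
            raise TreeSpecError(
                f"disallowed construct {type(sub).__name__} in condition {expr!r}"
            )
        if isinstance(sub, ast.Name) and sub.id not in CONDITION_FIELDS:
            raise TreeSpecError(f"unknown field {sub.id!r} in condition {expr!r}")
        if isinstance(sub, ast.Constant) and not isinstance(sub.value, (int, bool)):
            raise TreeSpecError(f"non-integer constant in condition {expr!r}")
    return compile(node, "<tree-rule>", "eval")


@dataclass(frozen=True)
class Rule:
    name: str
    level: PriorityLevel
    condition: str
    _code: object = field(repr=False, compare=False, default=None)


class TreeSpec:
    """Ordered first-match-wins rule list with a default level (total)."""

    def __init__(self, rules, default_level: PriorityLevel, version: str = "custom"):
        self.version = version
        self.default_level = default_level
        self.rules: list[Rule] = []
        for r in rules:
            code = _compile_condition(r.condition) if r._code is None else r._code
            self.rules.append(Rule(r.name, r.level, r.condition, code))

    def assign(self, v: ClassifierVector) -> PriorityLevel:
        env = v.as_env()
        for r in self.rules:
            if eval(r._code, {"__builtins__": {}}, env):  # noqa: S307 - validated AST
                return r.level
        return self.default_level

    def assign_env(self, env: dict) -> PriorityLevel:
        """Assign directly from an evaluation environment (bulk enumeration)."""
        for r in self.rules:
            if eval(r._code, {"__builtins__": {}}, env):  # noqa: S307
                return r.level
        return self.default_level

    @classmethod
    def from_yaml(cls, source) -> "TreeSpec":
        """Load a spec from a YAML file path or YAML text."""
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            raw = Path(source).read_text()
        else:
            raw = str(source)
        try:
            doc = yaml.safe_load(raw)
        except yaml.YAMLError as e:
            raise TreeSpecError(f"unreadable tree spec: {e}") from None
        if not isinstance(doc, dict) or "rules" not in doc:
            raise TreeSpecError("tree spec must be a mapping with a 'rules' list")
        try:
            default = PriorityLevel.from_label(doc.get("default_level", "low"))
            rules = [
                Rule(
                    name=r.get("name", f"rule{i}"),
                    level=PriorityLevel.from_label(r["level"]),
                    condition=r["when"],
                )
                for i, r in enumerate(doc["rules"])
            ]
        except (KeyError, TypeError, ValueError) as e:
            raise TreeSpecError(f"malformed tree spec: {e}") from None
        return cls(rules, default, version=doc.get("version", "custom"))


def default_tree() -> TreeSpec:
    """The shipped reference encoding of the MAPLe-AC tree."""
    text = resources.files("mapleac.data").joinpath("tree_default.yaml").read_text()
    return TreeSpec.from_yaml(text)


def assign_priority(v: ClassifierVector, spec: Optional[TreeSpec] = None) -> PriorityLevel:
    """Map one complete classifier vector to exactly one of five levels."""
    spec = spec or default_tree()
    return spec.assign(v)


def vector_from_assessment(a, baseline=None) -> ClassifierVector:
    """Classifier vector for one assessment.

    ``baseline`` is the pre-morbid assessment used for the ADL-decline risk
    category; ``None`` means the assessment *is* the pre-morbid one, whose
    decline category is false by definition (no earlier reference exists).
    """
    from .scales import adl_decline, institutional_risk_from_categories, risk_categories

    declined = False if baseline is None else adl_decline(baseline, a)

    def flag(code: str) -> bool:
        v = a.get(code)
        return bool(v) if v is not None else False

    return ClassifierVector(
        adl=adl_hierarchy(a),
        cps=cps_score(a),
        behavior=behavior_disturbance(a),
        decision_decline=flag("decision_making_decline"),
        medication_problem=flag("medication_management_problem"),
        pressure_ulcer=flag("pressure_ulcer"),
        fall=flag("fall_recent"),
        meal_prep_problem=flag("meal_preparation_problem"),
        swallowing_difficulty=flag("swallowing_difficulty"),
        inst_risk=institutional_risk_from_categories(risk_categories(a, declined)),
        screener=geriatric_screener(a),
    )


def classifier_vector(e: Episode, at: Timepoint) -> ClassifierVector:
    """Compute the tree's complete input for one episode time point.

    Raises :class:`~mapleac.scales.NonComputable` naming the blocking
    classifier when a scale-critical item (or required assessment) is
    missing.
    """
    a = e.assessment(at)
    if a is None:
        raise NonComputable("classifier_vector", [f"assessment:{at.label}"])
    baseline = None
    if at is not Timepoint.PREMORBID:
        baseline = e.assessment(Timepoint.PREMORBID)
        if baseline is None:
            raise NonComputable("inst_risk", ["assessment:premorbid"])
    return vector_from_assessment(a, baseline=baseline)


@dataclass
class ScoreResult:
    """Per-timepoint levels plus diagnostics for non-computable points."""

    levels: dict  # Timepoint -> PriorityLevel
    non_computable: dict  # Timepoint -> str reason
    tree_version: str


def score_episode(e: Episode, spec: Optional[TreeSpec] = None) -> ScoreResult:
    """Score every available time point; report the ones that cannot be."""
    spec = spec or default_tree()
    levels, problems = {}, {}
    for tp in Timepoint:
        if e.assessment(tp) is None:
            if tp is Timepoint.DAY7_OR_DISCHARGE:
                problems[tp] = "assessment not present"
            else:
                problems[tp] = "required assessment missing"
            continue
        try:
            levels[tp] = spec.assign(classifier_vector(e, tp))
        except NonComputable as exc:
            problems[tp] = str(exc)
    return ScoreResult(levels=levels, non_computable=problems, tree_version=spec.version)


def required_items(spec: Optional[TreeSpec] = None) -> frozenset:
    """Assessment items reachable from a spec through the subscales.

    Every vector field is computed by a registered classifier, so the
    reachable set is the union of the classifier item registries; the
    registry test asserts this equals the 31-item crosswalk.
    """
    items: set[str] = set()
    for clf in VECTOR_CLASSIFIERS:
        items.update(CLASSIFIER_ITEMS[clf])
    return frozenset(items)


def enumerate_environments(
    screener_values=range(0, 7),
) -> Iterator[dict]:
    """Enumerate the full discrete rule-evaluation grid.

    adl 0-6 x cps 0-6 x 7 boolean flags x risk count 0-8 x screener values.
    Yields evaluation environments (dicts) suitable for
    :meth:`TreeSpec.assign_env`.
    """
    flags = (
        "behavior",
        "decision_decline",
        "medication_problem",
        "pressure_ulcer",
        "fall",
        "meal_prep_problem",
        "swallowing_difficulty",
    )
    for adl, cps, fl, count, scr in itertools.product(
        range(7), range(7), itertools.product((False, True), repeat=len(flags)),
        range(N_RISK_CATEGORIES + 1), screener_values,
    ):
        env = {
            "adl": adl,
            "cps": cps,
            "inst_risk_count": count,
            "inst_risk_active": count >= 3,
            "screener": scr,
        }
        env.update(zip(flags, fl))
        yield env
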