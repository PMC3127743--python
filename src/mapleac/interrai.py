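"""Data model, codebook, and CSV I/O for interRAI-AC-style hospital episodes.

An episode is one acute-care admission of a person aged 75+, assessed at up
to three time points: pre-morbid status (30 days before admission),
admission status (24 h prior to admission), and status on day 7 or 24 h
pre-discharge, whichever comes first.  Each assessment carries the 31
crosswalk items the MAPLe-AC algorithm consumes; the episode additionally
carries demographics, reason for hospitalization, discharge and one-year
outcomes, and days to death (censored at 365).

The on-disk format is a wide CSV, one row per (patient_id, timepoint), with
episode-level fields repeated on every row; the missing sentinel is the
empty field.  The machine-readable codebook (item codes, value domains,
consumers) ships as YAML package data.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = None  # in-memory missing sentinel; empty field on disk


class Timepoint(enum.IntEnum):
    """The three episode assessment points, in temporal order."""

    PREMORBID = 0
    ADMISSION = 1
    DAY7_OR_DISCHARGE = 2

    @property
    def label(self) -> str:
        return _TIMEPOINT_LABELS[self]

    @classmethod
    def from_label(cls, s: str) -> "Timepoint":
        try:
            return _TIMEPOINT_BY_LABEL[s]
        except KeyError:
            raise ValueError(f"unknown timepoint label: {s!r}") from None


_TIMEPOINT_LABELS = {
    Timepoint.PREMORBID: "premorbid",
    Timepoint.ADMISSION: "admission",
    Timepoint.DAY7_OR_DISCHARGE: "day7_or_discharge",
}
_TIMEPOINT_BY_LABEL = {v: k for k, v in _TIMEPOINT_LABELS.items()}


class Sex(str, enum.Enum):
    WOMAN = "woman"
    MAN = "man"


class AgeGroup(str, enum.Enum):
    """Age bands; 75-79 is the reference band throughout the battery."""

    A75_79 = "75_79"
    A80_84 = "80_84"
    A85_89 = "85_89"
    A90_PLUS = "90_plus"


class Reason(str, enum.Enum):
    """Reason for hospitalization (crude co-morbidity adjuster)."""

    NEW_PROBLEM = "new_problem"
    EXACERBATION = "exacerbation"
    BOTH = "both"


class Outcome(str, enum.Enum):
    HOME = "home"
    INSTITUTION = "institution"
    DEAD = "dead"
    OTHER = "other"


# ADL self-performance: 0 independent .. 6 total dependence; 8 = activity
# did not occur during the look-back period.
ADL_DID_NOT_OCCUR = 8

# Item groups.  The four risk diagnoses are stored as separate items; the
# composite risk_diagnosis flag is derived (any of the four).
ADL_ITEMS = ("adl_hygiene", "adl_toilet_use", "adl_locomotion", "adl_eating")
COGNITION_ITEMS = (
    "comatose",
    "short_term_memory_problem",
    "decision_making",
    "making_self_understood",
)
BEHAVIOR_ITEMS = (
    "verbally_abusive",
    "physically_abusive",
    "socially_inappropriate",
    "resists_care",
)
CLINICAL_ITEMS = (
    "decision_making_decline",
    "medication_management_problem",
    "pressure_ulcer",
    "fall_recent",
    "meal_preparation_problem",
    "swallowing_difficulty",
)
RISK_DIAGNOSIS_ITEMS = ("dementia", "alzheimers", "multiple_sclerosis", "head_trauma")
RISK_ITEMS = (
    "prior_nursing_home",
    "goes_out",
    "bladder_incontinence",
    *RISK_DIAGNOSIS_ITEMS,
    "hygiene_or_bathing_problem",
    "delirium_indicator",
    "meal_shopping_problem",
)
SCREENER_ITEMS = (
    "phone_use_problem",
    "housework_problem",
    "finance_management_problem",
)

ALL_ITEMS: tuple[str, ...] = (
    ADL_ITEMS + COGNITION_ITEMS + BEHAVIOR_ITEMS + CLINICAL_ITEMS + RISK_ITEMS + SCREENER_ITEMS
)

# Items whose absence blocks a scale (never silently defaulted) vs boolean
# flags that default to "not present" with a warning.
SCALE_CRITICAL_ITEMS = frozenset(ADL_ITEMS + COGNITION_ITEMS)

#: classifier name -> items it consumes (many-to-many; eating feeds both
#: the ADL hierarchy and the CPS).
CLASSIFIER_ITEMS: dict[str, tuple[str, ...]] = {
    "adl_hierarchy": ADL_ITEMS,
    "cps": COGNITION_ITEMS + ("adl_eating",),
    "behavior": BEHAVIOR_ITEMS,
    "decision_decline": ("decision_making_decline",),
    "medication_problem": ("medication_management_problem",),
    "pressure_ulcer": ("pressure_ulcer",),
    "fall": ("fall_recent",),
    "meal_prep_problem": ("meal_preparation_problem",),
    "swallowing_difficulty": ("swallowing_difficulty",),
    "inst_risk": RISK_ITEMS,
    "screener": SCREENER_ITEMS
    + ("meal_preparation_problem", "medication_management_problem", "short_term_memory_problem"),
}


@dataclass(frozen=True)
class ItemDef:
    code: str
    group: str
    consumer: str
    domain: tuple[int, ...]
    label: str


class ItemMap:
    """The 31-item crosswalk: item codes, value domains, and consumers."""

    def __init__(self, items: Iterable[ItemDef]):
        self._items: dict[str, ItemDef] = {}
        for it in items:
            if it.code in self._items:
                raise ValueError(f"duplicate item code in codebook: {it.code}")
            self._items[it.code] = it

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, code: str) -> bool:
        return code in self._items

    def __iter__(self):
        return iter(self._items.values())

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._items)

    def domain(self, code: str) -> tuple[int, ...]:
        return self._items[code].domain

    def in_domain(self, code: str, value) -> bool:
        if value is MISSING:
            return True
        return value in self._items[code].domain

    def items_for(self, classifier: str) -> tuple[str, ...]:
        """Items a subscale/classifier consumes (many-to-many view)."""
        try:
            return CLASSIFIER_ITEMS[classifier]
        except KeyError:
            raise KeyError(f"unknown classifier: {classifier}") from None

    @classmethod
    def from_yaml(cls, path_or_text) -> "ItemMap":
        if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
            raw = Path(path_or_text).read_text()
        else:
            raw = str(path_or_text)
        doc = yaml.safe_load(raw)
        items = [
            ItemDef(
                code=d["code"],
                group=d["group"],
                consumer=d["consumer"],
                domain=tuple(d["domain"]),
                label=d.get("label", d["code"]),
            )
            for d in doc["items"]
        ]
        return cls(items)


def default_codebook() -> ItemMap:
    """The shipped 31-item crosswalk codebook."""
    text = resources.files("mapleac.data").joinpath("codebook.yaml").read_text()
    return ItemMap.from_yaml(text)


@dataclass
class Assessment:
    """One time point's item values for one patient.

    ``items`` maps item code -> coded value (int) or None (missing).
    Unknown keys are rejected at construction when ``codebook`` validation
    is used via :func:`read_episodes`; direct construction is permissive.
    """

    timepoint: Timepoint
    items: dict = field(default_factory=dict)

    def get(self, code: str):
        return self.items.get(code, MISSING)

    @property
    def risk_diagnosis(self) -> bool:
        """Any of dementia / Alzheimer's / multiple sclerosis / head trauma.

        Missing disease flags count as not present (boolean-flag policy).
        """
        return any(bool(self.get(c)) for c in RISK_DIAGNOSIS_ITEMS if self.get(c) is not MISSING)


@dataclass
class Episode:
    """One acute-care admission with up to three assessments and outcomes."""

    patient_id: str
    sex: Sex
    age_group: AgeGroup
    lived_alone: bool
    prior_hospitalization_90d: bool
    reason: Reason
    assessments: dict  # Timepoint -> Assessment
    discharge_outcome: Outcome
    one_year_outcome: Optional[Outcome]
    days_to_event: int
    event_died: bool
    # Diagnosis groups (ICD-10 chapters) used as Cox covariates.
    dx_neoplasms: bool = False
    dx_mental_behavioral: bool = False
    dx_respiratory: bool = False

    def __post_init__(self):
        if self.days_to_event < 0 or self.days_to_event > 365:
            raise ValueError(f"days_to_event out of range: {self.days_to_event}")
        if self.discharge_outcome is Outcome.DEAD and not self.event_died:
            raise ValueError("discharge_outcome DEAD requires event_died")

    def assessment(self, tp: Timepoint) -> Optional[Assessment]:
        return self.assessments.get(tp)


# ---------------------------------------------------------------------------
# Validation reporting


@dataclass
class ValidationReport:
    """Missing/out-of-domain items grouped by the classifier that needs them.

    ``blocking`` holds scale-critical problems (classifier non-computable);
    ``degraded`` holds boolean flags that will default to "not present".
    """

    blocking: dict = field(default_factory=dict)  # classifier -> [item...]
    degraded: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.blocking and not self.degraded

    def computable(self, classifier: str) -> bool:
        return classifier not in self.blocking


def validate_assessment(
    a: Assessment,
    required: Optional[set] = None,
    codebook: Optional[ItemMap] = None,
) -> ValidationReport:
    """Report every missing or out-of-domain item, per consuming classifier."""
    codebook = codebook or default_codebook()
    required = set(required) if required is not None else set(CLASSIFIER_ITEMS)
    rep = ValidationReport()
    for classifier in sorted(required):
        for code in CLASSIFIER_ITEMS[classifier]:
            v = a.get(code)
            bad = v is MISSING or not codebook.in_domain(code, v)
            if not bad:
                continue
            bucket = rep.blocking if code in SCALE_CRITICAL_ITEMS else rep.degraded
            bucket.setdefault(classifier, []).append(code)
    return rep


# ---------------------------------------------------------------------------
# CSV I/O

EPISODE_COLUMNS = (
    "patient_id",
    "timepoint",
    "sex",
    "age_group",
    "lived_alone",
    "prior_hosp_90d",
    "reason",
    "discharge_outcome",
    "one_year_outcome",
    "days_to_event",
    "event_died",
    "dx_neoplasms",
    "dx_mental_behavioral",
    "dx_respiratory",
)

CSV_COLUMNS = EPISODE_COLUMNS + ALL_ITEMS


class EpisodeCSVError(ValueError):
    """Hard error reading an episode CSV (header, duplicates)."""


@dataclass
class RowRejection:
    row: int
    patient_id: str
    reason: str


@dataclass
class ReadResult:
    episodes: list
    rejections: list


def _parse_bool(v) -> bool:
    return bool(int(v))


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return MISSING
    return int(v)


def read_episodes_with_report(path, codebook: Optional[ItemMap] = None) -> ReadResult:
    """Read an episode CSV, validating items against the codebook.

    Rows with out-of-domain item values are rejected with a diagnostic; an
    episode missing a required (pre-morbid or admission) row is rejected.
    Malformed headers and duplicate (patient_id, timepoint) pairs are hard
    errors.
    """
    codebook = codebook or default_codebook()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise EpisodeCSVError(f"malformed header: missing columns {missing_cols}")

    rejections: list[RowRejection] = []
    keys = list(zip(df["patient_id"], df["timepoint"]))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise EpisodeCSVError(f"duplicate (patient_id, timepoint) rows: {dupes[:5]}")

    rows_by_patient: dict[str, dict[Timepoint, tuple[int, pd.Series]]] = {}
    for idx, row in df.iterrows():
        pid = row["patient_id"]
        try:
            tp = Timepoint.from_label(row["timepoint"])
        except ValueError as e:
            rejections.append(RowRejection(int(idx), pid, str(e)))
            continue
        bad_item = None
        for code in ALL_ITEMS:
            v = _opt(row[code]) if row[code] != "" else MISSING
            if v is not MISSING and not codebook.in_domain(code, v):
                bad_item = (code, row[code])
                break
        if bad_item is not None:
            rejections.append(
                RowRejection(
                    int(idx), pid, f"item {bad_item[0]} value {bad_item[1]} out of domain"
                )
            )
            continue
        rows_by_patient.setdefault(pid, {})[tp] = (int(idx), row)

    episodes: list[Episode] = []
    for pid, tprows in rows_by_patient.items():
        required = {Timepoint.PREMORBID, Timepoint.ADMISSION}
        if not required <= set(tprows):
            missing = [tp.label for tp in sorted(required - set(tprows))]
            rejections.append(
                RowRejection(-1, pid, f"episode missing required timepoint rows: {missing}")
            )
            continue
        _, first = tprows[Timepoint.PREMORBID]
        try:
            assessments = {
                tp: Assessment(
                    timepoint=tp,
                    items={c: _opt(r[c]) if r[c] != "" else MISSING for c in ALL_ITEMS},
                )
                for tp, (_, r) in tprows.items()
            }
            ep = Episode(
                patient_id=pid,
                sex=Sex(first["sex"]),
                age_group=AgeGroup(first["age_group"]),
                lived_alone=_parse_bool(first["lived_alone"]),
                prior_hospitalization_90d=_parse_bool(first["prior_hosp_90d"]),
                reason=Reason(first["reason"]),
                assessments=assessments,
                discharge_outcome=Outcome(first["discharge_outcome"]),
                one_year_outcome=(
                    Outcome(first["one_year_outcome"]) if first["one_year_outcome"] else None
                ),
                days_to_event=int(first["days_to_event"]),
                event_died=_parse_bool(first["event_died"]),
                dx_neoplasms=_parse_bool(first["dx_neoplasms"]),
                dx_mental_behavioral=_parse_bool(first["dx_mental_behavioral"]),
                dx_respiratory=_parse_bool(first["dx_respiratory"]),
            )
        except (ValueError, KeyError) as e:
            rejections.append(RowRejection(-1, pid, f"invalid episode fields: {e}"))
            continue
        episodes.append(ep)

    for rej in rejections:
        logger.warning("rejected row %s (patient %s): %s", rej.row, rej.patient_id, rej.reason)
    episodes.sort(key=lambda e: e.patient_id)
    return ReadResult(episodes=episodes, rejections=rejections)


def read_episodes(path, codebook: Optional[ItemMap] = None) -> list:
    """Read episodes from CSV; rejected rows are logged (see module logger)."""
    return read_episodes_with_report(path, codebook).episodes


def episodes_to_frame(episodes: Iterable[Episode]) -> pd.DataFrame:
    """Flatten episodes to the wide one-row-per-(patient, timepoint) layout."""
    records = []
    for ep in episodes:
        base = {
            "patient_id": ep.patient_id,
            "sex": ep.sex.value,
            "age_group": ep.age_group.value,
            "lived_alone": int(ep.lived_alone),
            "prior_hosp_90d": int(ep.prior_hospitalization_90d),
            "reason": ep.reason.value,
            "discharge_outcome": ep.discharge_outcome.value,
            "one_year_outcome": ep.one_year_outcome.value if ep.one_year_outcome else "",
            "days_to_event": ep.days_to_event,
            "event_died": int(ep.event_died),
            "dx_neoplasms": int(ep.dx_neoplasms),
            "dx_mental_behavioral": int(ep.dx_mental_behavioral),
            "dx_respiratory": int(ep.dx_respiratory),
        }
        for tp in sorted(ep.assessments):
            a = ep.assessments[tp]
            rec = dict(base)
            rec["timepoint"] = tp.label
            for code in ALL_ITEMS:
                v = a.get(code)
                rec[code] = "" if v is MISSING else int(v)
            records.append(rec)
    df = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    return df


def write_episodes(episodes: Iterable[Episode], path) -> None:
    """Write episodes in the documented CSV dialect (UTF-8, empty = missing)."""
    episodes_to_frame(episodes).to_csv(path, index=False)
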