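"""Synthetic episode cohorts with the published marginal/effect structure.

The generator emulates the study conditions the algorithm was validated
under: demographics and per-timepoint priority-level marginals drawn from
the published cohort tables, binary outcomes drawn from logistic models
whose generating coefficients are the published multivariate odds ratios
(intercepts solved numerically so marginal outcome rates match), and
survival times drawn from an exponential proportional-hazards model whose
generating coefficients are the published hazard ratios (baseline rate
solved so the one-year death probability matches), censored at day 365.

Assessment item patterns are *inverse-constructed*: for each drawn priority
level the generator builds an item pattern that the active tree maps back
to exactly that level, and re-scores it to enforce the closed loop.  A
drawn level with no satisfying pattern under the active tree is a hard
error (generator/tree inconsistency), never a silent mismatch.

Covariates (sex, age group, reason, priority levels) are drawn
independently from their marginals: no joint distribution is published,
and independence is the simplest structure consistent with every printed
calibration number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .interrai import (
    ALL_ITEMS,
    AgeGroup,
    Assessment,
    Episode,
    Outcome,
    Reason,
    Sex,
    Timepoint,
)
from .tree import PriorityLevel, TreeSpec, default_tree, vector_from_assessment

__all__ = [
    "CohortParams",
    "GeneratedCohort",
    "OutcomeModelParams",
    "SurvivalModelParams",
    "generate_cohort",
    "inverse_construct_items",
    "load_profile",
    "solve_logistic_intercept",
    "solve_baseline_hazard",
]

_LEVELS = list(PriorityLevel)
_AGES = list(AgeGroup)
_REASONS = list(Reason)

#: covariate -> dummy indicator names (reference category first, no dummy).
AGE_DUMMIES = {
    AgeGroup.A80_84: "age_80_84",
    AgeGroup.A85_89: "age_85_89",
    AgeGroup.A90_PLUS: "age_90_plus",
}
REASON_DUMMIES = {Reason.EXACERBATION: "reason_exacerbation", Reason.BOTH: "reason_both"}


def design_indicators(
    sex: Sex,
    age: AgeGroup,
    reason: Reason,
    level: PriorityLevel,
    maple_reference: PriorityLevel,
) -> dict:
    """Dummy coding used by both the generator and the refits.

    References: man, age 75-79, new problem, and the endpoint's MAPLe
    reference level.
    """
    ind = {"sex_woman": int(sex is Sex.WOMAN)}
    for a, name in AGE_DUMMIES.items():
        ind[name] = int(age is a)
    for r, name in REASON_DUMMIES.items():
        ind[name] = int(reason is r)
    for lv in _LEVELS:
        if lv is not maple_reference:
            ind[f"maple_{lv.label}"] = int(level is lv)
    return ind


@dataclass
class OutcomeModelParams:
    """Generating logistic model for one binary endpoint."""

    name: str
    timepoint: Timepoint
    marginal_rate: float
    maple_reference: PriorityLevel
    log_odds: dict  # indicator name -> log OR
    conditional_on_survival: bool = False

    def linear_predictor(self, indicators: dict) -> float:
        return sum(b * indicators.get(k, 0) for k, b in self.log_odds.items())


@dataclass
class SurvivalModelParams:
    """Generating exponential proportional-hazards model for days to death."""

    timepoint: Timepoint
    one_year_death_rate: float
    maple_reference: PriorityLevel
    log_hr: dict  # indicator name -> log HR

    def linear_predictor(self, indicators: dict) -> float:
        return sum(b * indicators.get(k, 0) for k, b in self.log_hr.items())


@dataclass
class CohortParams:
    """Everything needed to generate one cohort reproducibly."""

    n: int
    seed: int
    name: str
    sex_p: dict  # Sex -> prob
    age_p: dict  # AgeGroup -> prob
    lived_alone_p: float
    prior_hosp_p: float
    reason_p: dict  # Reason -> prob
    level_p: dict  # Timepoint -> {PriorityLevel: prob}
    dx_prevalence: dict  # dx field -> prob
    outcome_models: dict  # name -> OutcomeModelParams
    survival_model: Optional[SurvivalModelParams]
    discharge_split: dict  # Outcome -> count (published marginals)
    one_year_split: Optional[dict]
    censor_day: int = 365

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for p in (self.sex_p, self.age_p, self.reason_p, *self.level_p.values()):
            total = sum(p.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginal probabilities sum to {total}, not 1")


@dataclass
class GeneratedCohort:
    episodes: list
    params: CohortParams
    provenance: dict = field(default_factory=dict)


def _norm(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def load_profile(profile, n: int, seed: int) -> CohortParams:
    """Build :class:`CohortParams` from a shipped profile name or a YAML path.

    Shipped profiles: ``nordic`` and ``canadian``.
    """
    if isinstance(profile, (str, Path)) and Path(str(profile)).suffix in {".yaml", ".yml"}:
        raw = Path(profile).read_text()
    else:
        try:
            raw = (
                resources.files("mapleac.data.profiles")
                .joinpath(f"{profile}.yaml")
                .read_text()
            )
        except FileNotFoundError:
            raise ValueError(f"unknown cohort profile: {profile!r}") from None
    doc = yaml.safe_load(raw)

    sex_p = _norm({Sex(k): v for k, v in doc["sex"].items()})
    age_p = _norm({AgeGroup(k): v for k, v in doc["age_group"].items()})
    reason_p = _norm({Reason(k): v for k, v in doc["reason"].items()})
    level_p = {
        Timepoint.from_label(tp): _norm(
            {PriorityLevel.from_label(k): v for k, v in counts.items()}
        )
        for tp, counts in doc["levels"].items()
    }
    n_profile = doc["profile_n"]

    outcome_models = {}
    for name, m in doc.get("outcome_models", {}).items():
        outcome_models[name] = OutcomeModelParams(
            name=name,
            timepoint=Timepoint.from_label(m["timepoint"]),
            marginal_rate=float(m["marginal_rate"]),
            maple_reference=PriorityLevel.from_label(m["maple_reference"]),
            log_odds={k: math.log(v) for k, v in m["odds_ratios"].items()},
            conditional_on_survival=bool(m.get("conditional_on_survival", False)),
        )

    survival = None
    if "survival_model" in doc:
        s = doc["survival_model"]
        survival = SurvivalModelParams(
            timepoint=Timepoint.from_label(s["timepoint"]),
            one_year_death_rate=float(s["one_year_death_rate"]),
            maple_reference=PriorityLevel.from_label(s["maple_reference"]),
            log_hr={k: math.log(v) for k, v in s["hazard_ratios"].items()},
        )

    return CohortParams(
        n=n,
        seed=seed,
        name=doc["name"],
        sex_p=sex_p,
        age_p=age_p,
        lived_alone_p=doc["lived_alone"] / n_profile,
        prior_hosp_p=doc["prior_hosp_90d"] / n_profile,
        reason_p=reason_p,
        level_p=level_p,
        dx_prevalence=dict(doc.get("dx_prevalence", {})),
        outcome_models=outcome_models,
        survival_model=survival,
        discharge_split={Outcome(k): v for k, v in doc["discharge_outcome"].items()},
        one_year_split=(
            {Outcome(k): v for k, v in doc["one_year_outcome"].items()}
            if "one_year_outcome" in doc
            else None
        ),
        censor_day=int(doc.get("censor_day", 365)),
    )


# ---------------------------------------------------------------------------
# Intercept / baseline-rate solvers


def _covariate_cells(params: CohortParams, timepoint: Timepoint, with_dx: bool):
    """Joint covariate cells and probabilities under independent marginals."""
    cells = []
    dx_fields = list(params.dx_prevalence) if with_dx else []
    for sex, ps in params.sex_p.items():
        for age, pa in params.age_p.items():
            for reason, pr in params.reason_p.items():
                for level, pl in params.level_p[timepoint].items():
                    base_p = ps * pa * pr * pl
                    if not dx_fields:
                        cells.append(((sex, age, reason, level, ()), base_p))
                        continue
                    for mask in range(1 << len(dx_fields)):
                        p = base_p
                        on = []
                        for i, f in enumerate(dx_fields):
                            q = params.dx_prevalence[f]
                            if mask >> i & 1:
                                p *= q
                                on.append(f)
                            else:
                                p *= 1 - q
                        cells.append(((sex, age, reason, level, tuple(on)), p))
    return cells


def solve_logistic_intercept(model: OutcomeModelParams, params: CohortParams) -> float:
    """Intercept making the expected marginal rate match the published one.

    Odds ratios are intercept-invariant, so generating effects are
    unaffected; solved by root finding on the expectation over the
    enumerable covariate joint.
    """
    cells = _covariate_cells(params, model.timepoint, with_dx=False)
    lps = np.array(
        [
            model.linear_predictor(
                design_indicators(sex, age, reason, level, model.maple_reference)
            )
            for (sex, age, reason, level, _), _ in cells
        ]
    )
    ps = np.array([p for _, p in cells])

    def gap(alpha):
        return float(ps @ expit(alpha + lps)) - model.marginal_rate

    return brentq(gap, -30.0, 30.0, xtol=1e-12)


def solve_baseline_hazard(model: SurvivalModelParams, params: CohortParams) -> float:
    """Baseline event rate (events/day) matching the one-year death probability."""
    cells = _covariate_cells(params, model.timepoint, with_dx=True)
    lps, ps = [], []
    for (sex, age, reason, level, dx_on), p in cells:
        ind = design_indicators(sex, age, reason, level, model.maple_reference)
        for f in dx_on:
            ind[f"dx_{f}"] = 1
        lps.append(model.linear_predictor(ind))
        ps.append(p)
    lps = np.array(lps)
    ps = np.array(ps)
    horizon = params.censor_day

    def gap(lam0):
        return float(ps @ (1.0 - np.exp(-lam0 * np.exp(lps) * horizon))) - model.one_year_death_rate

    return brentq(gap, 1e-12, 1.0, xtol=1e-15)


# ---------------------------------------------------------------------------
# Inverse construction of item patterns


def _base_items() -> dict:
    items = {code: 0 for code in ALL_ITEMS}
    items["goes_out"] = 1  # goes out of the house: no homebound risk
    return items


_SCREENER_CHOICES = ("phone_use_problem", "housework_problem", "finance_management_problem")
_BEHAVIOR_CHOICES = (
    "verbally_abusive",
    "physically_abusive",
    "socially_inappropriate",
    "resists_care",
)
#: per-assessment risk flags usable to activate the institutional screener
#: (independent of the cross-timepoint ADL-decline category).
_RISK_FLAG_CHOICES = (
    "prior_nursing_home",
    "bladder_incontinence",
    "hygiene_or_bathing_problem",
    "delirium_indicator",
    "meal_shopping_problem",
    "dementia",
)


def _set_adl(items: dict, score: int, rng: np.random.Generator) -> None:
    """Item pattern realizing a target ADL-hierarchy score."""
    if score == 0:
        return
    if score == 1:
        items["adl_hygiene"] = 2
    elif score == 2:
        items["adl_hygiene"] = 3
    elif score == 3:
        items["adl_hygiene"] = int(rng.integers(4, 7))
    elif score == 4:
        which = "adl_eating" if rng.integers(2) else "adl_locomotion"
        items[which] = int(rng.integers(4, 6))
    elif score == 5:
        items["adl_eating"] = 6
        items["adl_locomotion"] = 6
    else:
        for c in ("adl_hygiene", "adl_toilet_use", "adl_locomotion", "adl_eating"):
            items[c] = 6


def _set_cps(items: dict, score: int, rng: np.random.Generator) -> None:
    """Item pattern realizing a target CPS score (without touching ADLs
    except where the published scale itself requires eating dependence)."""
    if score == 0:
        return
    if score == 1:
        items["short_term_memory_problem"] = 1
    elif score == 2:
        items["short_term_memory_problem"] = 1
        items["making_self_understood"] = 1
    elif score == 3:
        items["short_term_memory_problem"] = 1
        items["decision_making"] = 2
    elif score == 4:
        items["short_term_memory_problem"] = 1
        items["decision_making"] = 2
        items["making_self_understood"] = 2
    elif score == 5:
        items["short_term_memory_problem"] = 1
        items["decision_making"] = 3
    else:
        items["comatose"] = 1


def _activate_risk(items: dict, rng: np.random.Generator) -> None:
    """Switch on three per-assessment risk categories (count >= 3)."""
    for c in rng.choice(len(_RISK_FLAG_CHOICES), size=3, replace=False):
        items[_RISK_FLAG_CHOICES[c]] = 1


def inverse_construct_items(
    level: PriorityLevel,
    spec: TreeSpec,
    rng: np.random.Generator,
    baseline: Optional[Assessment] = None,
    timepoint: Timepoint = Timepoint.PREMORBID,
) -> dict:
    """Item pattern that the active tree maps to exactly ``level``.

    ``baseline`` is the pre-morbid assessment (None at the pre-morbid
    point) so the closed-loop re-scoring accounts for the ADL-decline risk
    category.  Raises ``ValueError`` if the constructed pattern does not
    re-score to the requested level under ``spec``.
    """
    items = _base_items()
    if level is PriorityLevel.MILD:
        items[_SCREENER_CHOICES[rng.integers(len(_SCREENER_CHOICES))]] = 1
    elif level is PriorityLevel.MODERATE:
        driver = rng.integers(6)
        if driver == 0:
            _set_adl(items, int(rng.integers(1, 3)), rng)
        elif driver == 1:
            _set_cps(items, int(rng.integers(1, 3)), rng)
        elif driver == 2:
            items["fall_recent"] = 1
        elif driver == 3:
            items["swallowing_difficulty"] = 1
        elif driver == 4:
            items["medication_management_problem"] = 1
        else:
            items["decision_making_decline"] = 1
    elif level is PriorityLevel.HIGH:
        driver = rng.integers(5)
        if driver == 0:
            _set_adl(items, int(rng.integers(3, 7)), rng)
        elif driver == 1:
            _set_cps(items, int(rng.integers(3, 7)), rng)
        elif driver == 2:
            items[_BEHAVIOR_CHOICES[rng.integers(len(_BEHAVIOR_CHOICES))]] = 1
        elif driver == 3:
            items["pressure_ulcer"] = 1
        else:
            _activate_risk(items, rng)
    elif level is PriorityLevel.VERY_HIGH:
        _activate_risk(items, rng)
        driver = rng.integers(3)
        if driver == 0:
            _set_adl(items, int(rng.integers(4, 7)), rng)
        elif driver == 1:
            _set_cps(items, int(rng.integers(4, 7)), rng)
        else:
            items[_BEHAVIOR_CHOICES[rng.integers(len(_BEHAVIOR_CHOICES))]] = 1

    a = Assessment(timepoint=timepoint, items=items)
    scored = spec.assign(vector_from_assessment(a, baseline=baseline))
    if scored is not level:
        raise ValueError(
            f"generator/tree inconsistency: requested {level.label}, "
            f"pattern scores {scored.label} under spec {spec.version!r}"
        )
    return items


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(params: CohortParams, spec: Optional[TreeSpec] = None) -> GeneratedCohort:
    """Generate exactly ``params.n`` episodes; same params -> same cohort."""
    spec = spec or default_tree()
    rng = np.random.default_rng(params.seed)
    n = params.n

    sexes = list(params.sex_p)
    sex_idx = rng.choice(len(sexes), size=n, p=[params.sex_p[s] for s in sexes])
    ages = list(params.age_p)
    age_idx = rng.choice(len(ages), size=n, p=[params.age_p[a] for a in ages])
    reasons = list(params.reason_p)
    reason_idx = rng.choice(len(reasons), size=n, p=[params.reason_p[r] for r in reasons])
    alone = rng.random(n) < params.lived_alone_p
    prior = rng.random(n) < params.prior_hosp_p
    dx = {
        f: rng.random(n) < q for f, q in params.dx_prevalence.items()
    }  # field -> bool array

    level_draws = {}
    for tp, marg in params.level_p.items():
        lvls = list(marg)
        idx = rng.choice(len(lvls), size=n, p=[marg[lv] for lv in lvls])
        level_draws[tp] = [lvls[i] for i in idx]

    # Pre-solve intercepts and the baseline hazard.
    intercepts = {
        name: solve_logistic_intercept(m, params) for name, m in params.outcome_models.items()
    }
    lam0 = (
        solve_baseline_hazard(params.survival_model, params)
        if params.survival_model is not None
        else None
    )

    disch = params.discharge_split
    p_inst_vs_other = disch[Outcome.INSTITUTION] / (
        disch[Outcome.INSTITUTION] + disch[Outcome.OTHER]
    )
    if params.one_year_split is not None:
        oy = params.one_year_split
        p_oy_inst_vs_other = oy[Outcome.INSTITUTION] / (
            oy[Outcome.INSTITUTION] + oy[Outcome.OTHER]
        )

    episodes = []
    for i in range(n):
        sex, age, reason = sexes[sex_idx[i]], ages[age_idx[i]], reasons[reason_idx[i]]
        assessments = {}
        baseline = None
        for tp in Timepoint:
            if tp not in level_draws:
                continue
            items = inverse_construct_items(
                level_draws[tp][i], spec, rng, baseline=baseline, timepoint=tp
            )
            a = Assessment(timepoint=tp, items=items)
            assessments[tp] = a
            if tp is Timepoint.PREMORBID:
                baseline = a

        ep_dx = {f: bool(dx[f][i]) for f in dx}

        def indicators(model_tp, reference):
            ind = design_indicators(sex, age, reason, level_draws[model_tp][i], reference)
            for f, v in ep_dx.items():
                ind[f"dx_{f}"] = int(v)
            return ind

        # Survival (days to death, censored at censor_day).
        if lam0 is not None:
            sm = params.survival_model
            rate = lam0 * math.exp(sm.linear_predictor(indicators(sm.timepoint, sm.maple_reference)))
            t = rng.exponential(1.0 / rate)
            days = max(1, math.ceil(t))
            if days <= params.censor_day:
                event_died, days_to_event = True, days
            else:
                event_died, days_to_event = False, params.censor_day
        else:
            event_died, days_to_event = False, params.censor_day

        # Discharge outcome from the discharge-home logistic model.
        hm = params.outcome_models["discharge_home"]
        p_home = expit(
            intercepts["discharge_home"]
            + hm.linear_predictor(indicators(hm.timepoint, hm.maple_reference))
        )
        if rng.random() < p_home:
            discharge = Outcome.HOME
        elif event_died and days_to_event <= 60:
            discharge = Outcome.DEAD
        elif not event_died and lam0 is None and rng.random() < disch[Outcome.DEAD] / (
            disch[Outcome.DEAD] + disch[Outcome.INSTITUTION] + disch[Outcome.OTHER]
        ):
            discharge = Outcome.DEAD
            event_died = True
            days_to_event = int(rng.integers(1, 31))
        else:
            discharge = (
                Outcome.INSTITUTION if rng.random() < p_inst_vs_other else Outcome.OTHER
            )

        # One-year outcome (profiles without follow-up leave it missing).
        one_year = None
        if params.one_year_split is not None:
            if event_died:
                one_year = Outcome.DEAD
            else:
                om = params.outcome_models["home_one_year"]
                p_home_1y = expit(
                    intercepts["home_one_year"]
                    + om.linear_predictor(indicators(om.timepoint, om.maple_reference))
                )
                if rng.random() < p_home_1y:
                    one_year = Outcome.HOME
                else:
                    one_year = (
                        Outcome.INSTITUTION
                        if rng.random() < p_oy_inst_vs_other
                        else Outcome.OTHER
                    )

        episodes.append(
            Episode(
                patient_id=f"sim{i:07d}",
                sex=sex,
                age_group=age,
                lived_alone=bool(alone[i]),
                prior_hospitalization_90d=bool(prior[i]),
                reason=reason,
                assessments=assessments,
                discharge_outcome=discharge,
                one_year_outcome=one_year,
                days_to_event=days_to_event,
                event_died=event_died,
                dx_neoplasms=ep_dx.get("neoplasms", False),
                dx_mental_behavioral=ep_dx.get("mental_behavioral", False),
                dx_respiratory=ep_dx.get("respiratory", False),
            )
        )

    provenance = {
        "generator": "mapleac.synthetic",
        "profile": params.name,
        "n": n,
        "seed": params.seed,
        "tree_version": spec.version,
        "rng": "numpy PCG64 via default_rng(seed)",
    }
    return GeneratedCohort(episodes=episodes, params=params, provenance=provenance)


def draw_binary_endpoint(
    cohort: GeneratedCohort,
    model_name: str,
    seed: int,
    spec: Optional[TreeSpec] = None,
) -> np.ndarray:
    """Draw a standalone binary endpoint from a profile's generating model.

    Used for endpoints (e.g. adverse outcome at day 7/discharge) whose
    generating coefficient set is distinct from the default discharge-home
    model.  The covariate level is the episode's *scored* level at the
    model's time point.  Returns a boolean array aligned with the cohort's
    episodes (False where the time point is unavailable).
    """
    from .tree import classifier_vector

    spec = spec or default_tree()
    params = cohort.params
    model = params.outcome_models[model_name]
    alpha = solve_logistic_intercept(model, params)
    rng = np.random.default_rng(seed)
    out = np.zeros(len(cohort.episodes), dtype=bool)
    for i, ep in enumerate(cohort.episodes):
        if ep.assessment(model.timepoint) is None:
            continue
        level = spec.assign(classifier_vector(ep, model.timepoint))
        ind = design_indicators(ep.sex, ep.age_group, ep.reason, level, model.maple_reference)
        out[i] = rng.random() < expit(alpha + model.linear_predictor(ind))
    return out
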