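"""Predictive-validity battery: logistic ORs with c-statistics, ROC curves,
Cox proportional hazards for days to death, and cohort cross-tabulations.

Binary endpoints are defined by an :class:`EndpointSpec` mapping each
outcome category to positive / negative / excluded.  Covariates are
dummy-coded with the published reference categories: man, age 75-79, new
problem, and the endpoint's MAPLe reference level (very high for the
"home" endpoints, low for the adverse endpoints and the Cox model).
Reference categories are reported as estimate 1.00 with no interval; all
other estimates are exponentiated ML coefficients with 95% Wald intervals
on the log scale.

Both pseudo-R-squared variants are computed for logistic fits: Cox-Snell
("unscaled", the headline figure, matching the default R-square column of
the SAS logistic procedure the original analyses used) and the
max-rescaled (Nagelkerke) variant.  Cox ties are handled by the Efron
approximation by default (day-granularity survival data guarantees ties),
switchable to Breslow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .interrai import Episode, Outcome, Timepoint
from .scales import NonComputable
from .synthetic import AGE_DUMMIES, REASON_DUMMIES, design_indicators
from .tree import PriorityLevel, TreeSpec, classifier_vector, default_tree

logger = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a model fit."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(f"separation detected; offending covariate: {covariate}")


# ---------------------------------------------------------------------------
# Endpoints


@dataclass(frozen=True)
class EndpointSpec:
    """Binary endpoint: outcome field plus a disposition for each category."""

    name: str
    outcome_field: str  # "discharge_outcome" or "one_year_outcome"
    positive: frozenset
    negative: frozenset
    excluded: frozenset
    maple_reference: PriorityLevel

    def __post_init__(self):
        all_out = self.positive | self.negative | self.excluded
        if all_out != frozenset(Outcome) or (
            self.positive & self.negative
            or self.positive & self.excluded
            or self.negative & self.excluded
        ):
            raise ValueError("each outcome must map to exactly one disposition")

    def disposition(self, outcome: Optional[Outcome]) -> Optional[bool]:
        """True/False for positive/negative; None for excluded or missing."""
        if outcome is None or outcome in self.excluded:
            return None
        return outcome in self.positive


def _endpoint(name, fld, pos, neg, exc, ref) -> EndpointSpec:
    return EndpointSpec(
        name=name,
        outcome_field=fld,
        positive=frozenset(pos),
        negative=frozenset(neg),
        excluded=frozenset(exc),
        maple_reference=ref,
    )


def default_endpoints() -> dict:
    """The four published endpoints with their default dispositions.

    The published denominators (626 vs 137 = institution+dead+other for
    discharge home; 123 vs 640 = home+other for the adverse endpoint) fix
    the "other" category as negative on both sides.
    """
    H, I, D, O = Outcome.HOME, Outcome.INSTITUTION, Outcome.DEAD, Outcome.OTHER
    return {
        e.name: e
        for e in (
            _endpoint(
                "discharged_home", "discharge_outcome", {H}, {I, D, O}, set(), PriorityLevel.VERY_HIGH
            ),
            _endpoint(
                "adverse_at_discharge", "discharge_outcome", {I, D}, {H, O}, set(), PriorityLevel.LOW
            ),
            _endpoint(
                "home_at_one_year", "one_year_outcome", {H}, {I, D, O}, set(), PriorityLevel.VERY_HIGH
            ),
            _endpoint(
                "adverse_at_one_year", "one_year_outcome", {I, D}, {H, O}, set(), PriorityLevel.LOW
            ),
        )
    }


def endpoints_from_yaml(source) -> dict:
    """Load endpoint definitions from a YAML mapping (CLI config surface)."""
    doc = yaml.safe_load(source if "\n" in str(source) else open(source).read())
    out = {}
    for name, e in doc.items():
        out[name] = _endpoint(
            name,
            e["outcome_field"],
            {Outcome(v) for v in e.get("positive", [])},
            {Outcome(v) for v in e.get("negative", [])},
            {Outcome(v) for v in e.get("excluded", [])},
            PriorityLevel.from_label(e["maple_reference"]),
        )
    return out


# ---------------------------------------------------------------------------
# Results containers


@dataclass
class Term:
    covariate: str
    level: str
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    is_reference: bool = False


@dataclass
class ModelResult:
    """Fitted effects as ORs/HRs with CIs, fit statistics, and provenance."""

    name: str
    model_kind: str  # "logistic" or "cox"
    terms: list
    pseudo_r2: Optional[dict]
    c_statistic: Optional[float]
    n_positive: int
    n_negative: int
    provenance: dict = field(default_factory=dict)

    def term(self, covariate: str, level: str) -> Term:
        for t in self.terms:
            if t.covariate == covariate and t.level == level:
                return t
        raise KeyError((covariate, level))

    def estimate(self, covariate: str, level: str) -> float:
        return self.term(covariate, level).estimate

    def summary(self) -> str:
        lines = [
            f"{self.model_kind.upper()} model: {self.name} "
            f"(n+={self.n_positive}, n-={self.n_negative})"
        ]
        kind = "OR" if self.model_kind == "logistic" else "HR"
        for t in self.terms:
            if t.is_reference:
                lines.append(f"  {t.covariate} {t.level:<12} 1.00 (reference)")
            else:
                lines.append(
                    f"  {t.covariate} {t.level:<12} {kind}={t.estimate:6.2f} "
                    f"({t.ci_low:.2f}-{t.ci_high:.2f}) p={t.p_value:.3g}"
                )
        if self.pseudo_r2 is not None:
            lines.append(
                f"  R-square {100 * self.pseudo_r2['cox_snell']:.1f}% "
                f"(max-rescaled {100 * self.pseudo_r2['nagelkerke']:.1f}%)"
            )
        if self.c_statistic is not None:
            lines.append(f"  c-statistic (AUC) {self.c_statistic:.2f}")
        return "\n".join(lines)


@dataclass
class RocCurve:
    points: np.ndarray  # (k, 2) array of (fpr, tpr), (0,0) .. (1,1)
    auc: float


# ---------------------------------------------------------------------------
# Design-matrix assembly

_COLUMN_TERMS = {
    "sex_woman": ("sex", "woman"),
    "age_80_84": ("age", "80_84"),
    "age_85_89": ("age", "85_89"),
    "age_90_plus": ("age", "90_plus"),
    "reason_exacerbation": ("reason", "exacerbation"),
    "reason_both": ("reason", "both"),
    "dx_neoplasms": ("diagnosis", "neoplasms"),
    "dx_mental_behavioral": ("diagnosis", "mental_behavioral"),
    "dx_respiratory": ("diagnosis", "respiratory"),
}
for lv in PriorityLevel:
    _COLUMN_TERMS[f"maple_{lv.label}"] = ("maple", lv.label)

DEFAULT_COVARIATES = ("sex", "age", "reason", "maple")


def score_levels(
    cohort: Iterable[Episode], at: Timepoint, spec: Optional[TreeSpec] = None
) -> tuple[list, list]:
    """Priority level at one time point per episode (None if non-computable)."""
    spec = spec or default_tree()
    levels, problems = [], []
    for ep in cohort:
        try:
            levels.append(spec.assign(classifier_vector(ep, at)))
        except NonComputable as exc:
            levels.append(None)
            problems.append((ep.patient_id, str(exc)))
    return levels, problems


def _design_frame(
    episodes: Sequence[Episode],
    levels: Sequence[PriorityLevel],
    maple_reference: PriorityLevel,
    covariates: Sequence[str],
) -> pd.DataFrame:
    cols: list[str] = []
    if "sex" in covariates:
        cols.append("sex_woman")
    if "age" in covariates:
        cols.extend(AGE_DUMMIES.values())
    if "reason" in covariates:
        cols.extend(REASON_DUMMIES.values())
    if "maple" in covariates:
        cols.extend(f"maple_{lv.label}" for lv in PriorityLevel if lv is not maple_reference)
    if "diagnosis" in covariates:
        cols.extend(("dx_neoplasms", "dx_mental_behavioral", "dx_respiratory"))
    rows = []
    for ep, lv in zip(episodes, levels):
        ind = design_indicators(ep.sex, ep.age_group, ep.reason, lv, maple_reference)
        ind["dx_neoplasms"] = int(ep.dx_neoplasms)
        ind["dx_mental_behavioral"] = int(ep.dx_mental_behavioral)
        ind["dx_respiratory"] = int(ep.dx_respiratory)
        rows.append([ind[c] for c in cols])
    return pd.DataFrame(rows, columns=cols, dtype=float)


def _terms_from_fit(
    columns: Sequence[str],
    params: np.ndarray,
    bse: np.ndarray,
    pvalues: np.ndarray,
    maple_reference: PriorityLevel,
    covariates: Sequence[str],
) -> list:
    by_col = {
        c: Term(
            covariate=_COLUMN_TERMS[c][0],
            level=_COLUMN_TERMS[c][1],
            estimate=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            p_value=float(p),
        )
        for c, b, se, p in zip(columns, params, bse, pvalues)
    }
    terms: list[Term] = []
    if "sex" in covariates:
        terms.append(by_col["sex_woman"])
    if "age" in covariates:
        terms.append(Term("age", "75_79", 1.0, is_reference=True))
        terms.extend(by_col[c] for c in AGE_DUMMIES.values())
    if "reason" in covariates:
        terms.append(Term("reason", "new_problem", 1.0, is_reference=True))
        terms.extend(by_col[c] for c in REASON_DUMMIES.values())
    if "maple" in covariates:
        for lv in PriorityLevel:
            if lv is maple_reference:
                terms.append(Term("maple", lv.label, 1.0, is_reference=True))
            else:
                terms.append(by_col[f"maple_{lv.label}"])
    if "diagnosis" in covariates:
        terms.extend(
            by_col[c] for c in ("dx_neoplasms", "dx_mental_behavioral", "dx_respiratory")
        )
    return terms


def _check_separation(columns, params, bse, threshold=15.0):
    bad = [c for c, b, se in zip(columns, params, bse) if abs(b) > threshold or not np.isfinite(se)]
    if bad:
        raise SeparationError(bad[0])


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores, outcomes=None) -> RocCurve:
    """ROC curve over all distinct thresholds and its trapezoidal AUC.

    Accepts either parallel arrays ``(scores, outcomes)`` or a single
    iterable of (score, outcome) pairs.  The trapezoidal AUC equals the
    Mann-Whitney concordance probability with ties counted one half.
    """
    if outcomes is None:
        pairs = list(scores)
        s = np.asarray([p[0] for p in pairs], dtype=float)
        y = np.asarray([bool(p[1]) for p in pairs])
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(outcomes, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("ROC requires at least one positive and one negative outcome")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=points, auc=auc)


# ---------------------------------------------------------------------------
# Model fits


def fit_logistic(
    cohort: Sequence[Episode],
    endpoint: EndpointSpec,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    at: Timepoint = Timepoint.PREMORBID,
    spec: Optional[TreeSpec] = None,
) -> ModelResult:
    """Multivariate logistic fit of one binary endpoint.

    Episodes with a non-computable level at ``at`` or an excluded/missing
    outcome are dropped (logged).  Returns exponentiated coefficients with
    95% Wald CIs, both pseudo-R-squared variants, and the c-statistic of
    the fitted probabilities.
    """
    spec = spec or default_tree()
    levels, problems = score_levels(cohort, at, spec)
    kept_eps, kept_lv, y = [], [], []
    for ep, lv in zip(cohort, levels):
        if lv is None:
            continue
        disp = endpoint.disposition(getattr(ep, endpoint.outcome_field))
        if disp is None:
            continue
        kept_eps.append(ep)
        kept_lv.append(lv)
        y.append(disp)
    y = np.asarray(y, dtype=float)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"endpoint {endpoint.name}: single-class outcome after exclusions")
    if problems:
        logger.info("%d episodes dropped as non-computable at %s", len(problems), at.label)

    X = _design_frame(kept_eps, kept_lv, endpoint.maple_reference, covariates)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(str(exc)) from exc
    cols = list(X.columns)
    params = np.asarray(fit.params)[1:]
    bse = np.asarray(fit.bse)[1:]
    pvals = np.asarray(fit.pvalues)[1:]
    _check_separation(cols, params, bse)

    n = len(y)
    lr = 2.0 * (fit.llf - fit.llnull)
    cox_snell = 1.0 - float(np.exp(-lr / n))
    max_cs = 1.0 - float(np.exp(2.0 * fit.llnull / n))
    pseudo = {"cox_snell": cox_snell, "nagelkerke": cox_snell / max_cs}
    c_stat = roc_auc(np.asarray(fit.predict(Xc)), y.astype(bool)).auc

    return ModelResult(
        name=endpoint.name,
        model_kind="logistic",
        terms=_terms_from_fit(cols, params, bse, pvals, endpoint.maple_reference, covariates),
        pseudo_r2=pseudo,
        c_statistic=c_stat,
        n_positive=n_pos,
        n_negative=n_neg,
        provenance={
            "timepoint": at.label,
            "tree_version": spec.version,
            "n_dropped_non_computable": len(problems),
            "n_excluded_outcome": len(list(cohort)) - len(problems) - n,
        },
    )


def fit_cox(
    cohort: Sequence[Episode],
    covariates: Sequence[str] = DEFAULT_COVARIATES + ("diagnosis",),
    at: Timepoint = Timepoint.PREMORBID,
    spec: Optional[TreeSpec] = None,
    ties: str = "efron",
    maple_reference: PriorityLevel = PriorityLevel.LOW,
) -> ModelResult:
    """Cox proportional-hazards fit of days to death (censored at 365).

    Partial-likelihood estimates with the Efron tie correction by default
    (``ties="breslow"`` switches); HRs are exponentiated coefficients with
    95% Wald CIs.
    """
    spec = spec or default_tree()
    levels, problems = score_levels(cohort, at, spec)
    kept = [(ep, lv) for ep, lv in zip(cohort, levels) if lv is not None]
    if not kept:
        raise ValueError("no scorable episodes")
    eps = [e for e, _ in kept]
    lvs = [lv for _, lv in kept]
    days = np.array([e.days_to_event for e in eps], dtype=float)
    status = np.array([e.event_died for e in eps], dtype=float)
    n_events = int(status.sum())
    if n_events == 0:
        raise ValueError("no death events; Cox model not estimable")

    X = _design_frame(eps, lvs, maple_reference, covariates)
    model = sm.PHReg(days, X, status=status, ties=ties)
    fit = model.fit()
    cols = list(X.columns)
    _check_separation(cols, fit.params, fit.bse)

    return ModelResult(
        name="days_to_death",
        model_kind="cox",
        terms=_terms_from_fit(cols, fit.params, fit.bse, fit.pvalues, maple_reference, covariates),
        pseudo_r2=None,
        c_statistic=None,
        n_positive=n_events,
        n_negative=int(len(eps) - n_events),
        provenance={
            "timepoint": at.label,
            "tree_version": spec.version,
            "ties": ties,
            "n_dropped_non_computable": len(problems),
        },
    )


# ---------------------------------------------------------------------------
# Cross-tabulation


@dataclass
class CrosstabResult:
    statistic: float
    p_value: float
    dof: int
    table: pd.DataFrame


def _values(cohort, variable):
    if callable(variable):
        vals = [variable(e) for e in cohort]
    else:
        vals = [getattr(e, variable) for e in cohort]
    return [v.value if hasattr(v, "value") else v for v in vals]


def crosstab_compare(a, b, variable) -> CrosstabResult:
    """Pearson chi-squared comparison of a categorical variable's
    distribution between two cohorts (df = (r-1)(c-1), no continuity
    correction)."""
    if not len(a) or not len(b):
        raise ValueError("both cohorts must be non-empty")
    va, vb = _values(a, variable), _values(b, variable)
    cats = sorted(set(va) | set(vb), key=str)
    table = pd.DataFrame(
        [[va.count(c) for c in cats], [vb.count(c) for c in cats]],
        index=["cohort_a", "cohort_b"],
        columns=[str(c) for c in cats],
    )
    obs = table.to_numpy()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected == 0).any():
        raise ValueError(f"zero expected cell count in contingency table:\n{table}")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return CrosstabResult(statistic=float(stat), p_value=float(p), dof=int(dof), table=table)


# ---------------------------------------------------------------------------
# Reports


@dataclass
class Report:
    """Machine- and human-readable views of a set of model results."""

    terms: pd.DataFrame
    models: pd.DataFrame

    def to_csv(self, terms_path, models_path) -> None:
        self.terms.to_csv(terms_path, index=False)
        self.models.to_csv(models_path, index=False)

    def to_text(self) -> str:
        if self.models.empty:
            return "model,kind,n_positive,n_negative\n(no results)"
        out = []
        for _, row in self.models.iterrows():
            out.append(
                f"== {row['model']} ({row['kind']}; "
                f"n+={row['n_positive']}, n-={row['n_negative']}) =="
            )
            sub = self.terms[self.terms["model"] == row["model"]]
            for _, t in sub.iterrows():
                if t["is_reference"]:
                    out.append(f"  {t['covariate']:<10} {t['level']:<16} 1.00")
                else:
                    out.append(
                        f"  {t['covariate']:<10} {t['level']:<16} {t['estimate']:.2f} "
                        f"({t['ci_low']:.2f}-{t['ci_high']:.2f})"
                    )
        return "\n".join(out)


TERM_COLUMNS = (
    "model",
    "kind",
    "covariate",
    "level",
    "estimate",
    "ci_low",
    "ci_high",
    "p_value",
    "is_reference",
)
MODEL_COLUMNS = (
    "model",
    "kind",
    "n_positive",
    "n_negative",
    "r2_cox_snell_pct",
    "r2_nagelkerke_pct",
    "c_statistic",
    "timepoint",
    "tree_version",
)


def report_tables(results: Sequence[ModelResult]) -> Report:
    """Assemble per-endpoint effect and fit-statistic tables."""
    trows, mrows = [], []
    for r in results:
        for t in r.terms:
            trows.append(
                {
                    "model": r.name,
                    "kind": r.model_kind,
                    "covariate": t.covariate,
                    "level": t.level,
                    "estimate": t.estimate,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                    "is_reference": t.is_reference,
                }
            )
        mrows.append(
            {
                "model": r.name,
                "kind": r.model_kind,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
                "r2_cox_snell_pct": (
                    100 * r.pseudo_r2["cox_snell"] if r.pseudo_r2 else np.nan
                ),
                "r2_nagelkerke_pct": (
                    100 * r.pseudo_r2["nagelkerke"] if r.pseudo_r2 else np.nan
                ),
                "c_statistic": r.c_statistic if r.c_statistic is not None else np.nan,
                "timepoint": r.provenance.get("timepoint", ""),
                "tree_version": r.provenance.get("tree_version", ""),
            }
        )
    return Report(
        terms=pd.DataFrame(trows, columns=TERM_COLUMNS),
        models=pd.DataFrame(mrows, columns=MODEL_COLUMNS),
    )


def read_report_csv(terms_path, models_path) -> Report:
    """Re-parse a written report (round-trips the numeric values)."""
    return Report(
        terms=pd.read_csv(terms_path),
        models=pd.read_csv(models_path),
    )
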