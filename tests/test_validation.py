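"""Validation battery: AUC oracle equivalence, model fits, cross-tabs, reports."""

import numpy as np
import pytest

from mapleac.interrai import Outcome, Timepoint
from mapleac.synthetic import generate_cohort, load_profile
from mapleac.validation import (
    SeparationError,
    crosstab_compare,
    default_endpoints,
    fit_cox,
    fit_logistic,
    read_report_csv,
    report_tables,
    roc_auc,
)

from .oracles import pairwise_auc


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert curve.auc == 1.0

    def test_chance_level_for_uninformative_scores(self):
        rng = np.random.default_rng(0)
        s = rng.random(10_000)
        y = rng.random(10_000) < 0.4
        assert abs(roc_auc(s, y).auc - 0.5) < 0.02

    def test_trapezoid_equals_pairwise_concordance_oracle(self):
        """Trapezoidal AUC == O(n^2) tie-aware concordance on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            s = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert abs(roc_auc(s, y).auc - pairwise_auc(s, y)) < 1e-12

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.random(500), rng.random(500) < 0.3)
        pts = curve.points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_score_shift_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.random(300)
        y = rng.random(300) < 0.4
        a, b = roc_auc(s, y), roc_auc(s + 17.5, y)
        assert a.auc == b.auc
        assert np.array_equal(a.points, b.points)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_accepts_pair_iterable(self):
        pairs = [(0.9, True), (0.1, False), (0.5, True)]
        assert roc_auc(pairs).auc == roc_auc([0.9, 0.1, 0.5], [True, False, True]).auc


class TestFitLogistic:
    def test_reference_rows_are_exactly_one(self, nordic_episodes, tree):
        res = fit_logistic(
            nordic_episodes, default_endpoints()["discharged_home"],
            at=Timepoint.PREMORBID, spec=tree,
        )
        refs = [t for t in res.terms if t.is_reference]
        assert {(t.covariate, t.level) for t in refs} == {
            ("age", "75_79"), ("reason", "new_problem"), ("maple", "very_high")
        }
        assert all(t.estimate == 1.0 and t.ci_low is None for t in refs)

    def test_ci_brackets_estimate(self, nordic_episodes, tree):
        res = fit_logistic(
            nordic_episodes, default_endpoints()["discharged_home"],
            at=Timepoint.PREMORBID, spec=tree,
        )
        for t in res.terms:
            if not t.is_reference:
                assert t.ci_low <= t.estimate <= t.ci_high

    def test_null_covariates_near_one(self, nordic_episodes, tree):
        """Diagnosis flags don't enter the generating discharge model."""
        res = fit_logistic(
            nordic_episodes, default_endpoints()["discharged_home"],
            covariates=("sex", "age", "reason", "maple", "diagnosis"),
            at=Timepoint.PREMORBID, spec=tree,
        )
        for level in ("neoplasms", "mental_behavioral", "respiratory"):
            t = res.term("diagnosis", level)
            assert t.ci_low < 1.0 < t.ci_high

    def test_training_c_statistic_at_least_half(self, nordic_episodes, tree):
        for name, ep_spec in default_endpoints().items():
            res = fit_logistic(nordic_episodes, ep_spec, at=Timepoint.PREMORBID, spec=tree)
            assert res.c_statistic >= 0.5, name

    def test_pseudo_r2_variants_ordered(self, nordic_episodes, tree):
        res = fit_logistic(
            nordic_episodes, default_endpoints()["adverse_at_discharge"],
            at=Timepoint.PREMORBID, spec=tree,
        )
        assert 0 < res.pseudo_r2["cox_snell"] < res.pseudo_r2["nagelkerke"] < 1

    def test_single_class_endpoint_rejected(self, nordic_episodes, tree):
        from mapleac.validation import EndpointSpec
        from mapleac.tree import PriorityLevel

        everything_positive = EndpointSpec(
            name="degenerate",
            outcome_field="discharge_outcome",
            positive=frozenset(Outcome),
            negative=frozenset(),
            excluded=frozenset(),
            maple_reference=PriorityLevel.LOW,
        )
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(nordic_episodes, everything_positive, spec=tree)

    def test_complete_separation_reported(self, tree):
        """An endpoint perfectly determined by a covariate names the culprit."""
        cohort = generate_cohort(load_profile("nordic", n=400, seed=5), tree).episodes
        for e in cohort:  # make outcome a deterministic function of sex
            e.discharge_outcome = (
                Outcome.HOME if e.sex.value == "woman" else Outcome.INSTITUTION
            )
            if e.event_died:
                e.event_died = False
                e.days_to_event = 365
        with pytest.raises(SeparationError):
            fit_logistic(cohort, default_endpoints()["discharged_home"], spec=tree)

    def test_or_coverage_over_replicates(self, tree):
        """Generating OR falls inside the recovered 95% CI at ~nominal rate.

        40 replicates at n = 3000; the pass bound (>=80%) has ~1e-3
        violation probability under nominal 95% coverage.
        """
        endpoint = default_endpoints()["discharged_home"]
        hits = 0
        for rep in range(40):
            cohort = generate_cohort(load_profile("nordic", n=3000, seed=3000 + rep), tree)
            res = fit_logistic(cohort.episodes, endpoint, at=Timepoint.PREMORBID, spec=tree)
            t = res.term("maple", "low")
            if t.ci_low <= 12.20 <= t.ci_high:
                hits += 1
        assert hits >= 32


class TestFitCox:
    def test_reference_and_ci_structure(self, nordic_episodes, tree):
        res = fit_cox(nordic_episodes, at=Timepoint.PREMORBID, spec=tree)
        assert res.model_kind == "cox"
        ref = res.term("maple", "low")
        assert ref.is_reference and ref.estimate == 1.0
        for t in res.terms:
            if not t.is_reference:
                assert t.ci_low <= t.estimate <= t.ci_high

    def test_admission_levels_are_null_for_survival(self, nordic_episodes, tree):
        """Survival is generated from pre-morbid levels; admission levels are
        drawn independently, so their HRs hover near 1."""
        res = fit_cox(nordic_episodes, at=Timepoint.ADMISSION, spec=tree)
        for lv in ("mild", "moderate", "high", "very_high"):
            assert 0.5 < res.estimate("maple", lv) < 2.0

    def test_time_scale_invariance(self, tree):
        """Doubling all survival times (censoring rescaled) leaves HRs fixed."""
        params = load_profile("nordic", n=1200, seed=31)
        params.censor_day = 180
        cohort = generate_cohort(params, tree).episodes
        doubled = []
        for e in cohort:
            d = type(e)(**{**vars(e), "days_to_event": 2 * e.days_to_event})
            doubled.append(d)
        a = fit_cox(cohort, at=Timepoint.PREMORBID, spec=tree)
        b = fit_cox(doubled, at=Timepoint.PREMORBID, spec=tree)
        for ta, tb in zip(a.terms, b.terms):
            if not ta.is_reference:
                assert ta.estimate == pytest.approx(tb.estimate, rel=1e-8)

    def test_agrees_with_lifelines(self, nordic_episodes, tree):
        """Independent cross-check: lifelines Efron fit gives the same HRs."""
        from lifelines import CoxPHFitter

        from mapleac.tree import PriorityLevel
        from mapleac.validation import _design_frame, score_levels

        levels, _ = score_levels(nordic_episodes, Timepoint.PREMORBID, tree)
        X = _design_frame(
            nordic_episodes, levels, PriorityLevel.LOW,
            ("sex", "age", "reason", "maple", "diagnosis"),
        )
        df = X.copy()
        df["T"] = [e.days_to_event for e in nordic_episodes]
        df["E"] = [e.event_died for e in nordic_episodes]
        ll = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        ours = fit_cox(nordic_episodes, at=Timepoint.PREMORBID, spec=tree)
        for col in X.columns:
            cov, lv = col.split("_", 1)
            lookup = {"maple": ("maple", lv[len(""):]), "dx": ("diagnosis", lv)}
            if col.startswith("maple_"):
                t = ours.term("maple", col[len("maple_"):])
            elif col.startswith("dx_"):
                t = ours.term("diagnosis", col[len("dx_"):])
            elif col == "sex_woman":
                t = ours.term("sex", "woman")
            elif col.startswith("age_"):
                t = ours.term("age", col[len("age_"):])
            else:
                t = ours.term("reason", col[len("reason_"):])
            assert t.estimate == pytest.approx(float(np.exp(ll.params_[col])), rel=1e-4)

    def test_no_events_rejected(self, nordic_episodes, tree):
        immortal = []
        for e in nordic_episodes[:80]:
            d = type(e)(**{**vars(e), "event_died": False, "days_to_event": 365,
                           "discharge_outcome": Outcome.HOME})
            immortal.append(d)
        with pytest.raises(ValueError, match="no death events"):
            fit_cox(immortal, spec=tree)


class TestCrosstab:
    def test_identical_cohorts_give_zero_statistic(self, nordic_episodes):
        r = crosstab_compare(nordic_episodes[:200], nordic_episodes[:200], "sex")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_disjoint_two_by_two_table(self, nordic_episodes):
        """A (10,0;0,10) table scores the hand-computed Pearson value 20."""
        women = [e for e in nordic_episodes if e.sex.value == "woman"][:10]
        men = [e for e in nordic_episodes if e.sex.value == "man"][:10]
        r = crosstab_compare(women, men, "sex")
        assert r.statistic == pytest.approx(20.0)
        assert r.dof == 1

    def test_category_permutation_invariance(self, nordic_episodes):
        a, b = nordic_episodes[:300], nordic_episodes[300:600]
        r1 = crosstab_compare(a, b, "age_group")
        r2 = crosstab_compare(b, a, "age_group")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_empty_cohort_rejected(self, nordic_episodes):
        with pytest.raises(ValueError):
            crosstab_compare([], nordic_episodes[:5], "sex")


class TestReports:
    def test_empty_result_list_gives_headed_empty_report(self):
        rep = report_tables([])
        assert rep.terms.empty and rep.models.empty
        assert "model" in rep.terms.columns

    def test_csv_round_trip(self, tmp_path, nordic_episodes, tree):
        res = [
            fit_logistic(
                nordic_episodes, default_endpoints()["discharged_home"],
                at=Timepoint.PREMORBID, spec=tree,
            ),
            fit_cox(nordic_episodes, at=Timepoint.PREMORBID, spec=tree),
        ]
        rep = report_tables(res)
        rep.to_csv(tmp_path / "terms.csv", tmp_path / "models.csv")
        back = read_report_csv(tmp_path / "terms.csv", tmp_path / "models.csv")
        assert np.allclose(
            back.terms["estimate"].to_numpy(), rep.terms["estimate"].to_numpy()
        )
        assert list(back.models["model"]) == list(rep.models["model"])

    def test_report_carries_tree_version(self, nordic_episodes, tree):
        res = fit_logistic(
            nordic_episodes, default_endpoints()["discharged_home"], spec=tree
        )
        rep = report_tables([res])
        assert (rep.models["tree_version"] == tree.version).all()
        assert "== discharged_home" in rep.to_text().splitlines()[0]
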