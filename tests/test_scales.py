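"""Subscale correctness: exhaustive agreement with the published grids."""

import itertools

import pytest

from mapleac.scales import (
    N_RISK_CATEGORIES,
    NonComputable,
    SCREENER_FLAG_ITEMS,
    adl_decline,
    adl_hierarchy,
    behavior_disturbance,
    cps_score,
    geriatric_screener,
    institutional_risk_from_categories,
    risk_categories,
)

from .conftest import make_assessment
from .oracles import adl_hierarchy_oracle, cps_oracle

ADL_CODES = (0, 1, 2, 3, 4, 5, 6, 8)


class TestCps:
    def test_intact(self):
        assert cps_score(make_assessment()) == 0

    def test_comatose_dominates(self):
        a = make_assessment(comatose=1, adl_eating=0)
        assert cps_score(a) == 6

    @pytest.mark.parametrize("eating,expected", [(6, 6), (8, 6), (0, 5), (3, 5)])
    def test_severe_decision_impairment_splits_on_eating(self, eating, expected):
        a = make_assessment(decision_making=3, adl_eating=eating)
        assert cps_score(a) == expected

    def test_agrees_with_lookup_oracle_exhaustively(self):
        """Procedural CPS equals the grid transcription on every input."""
        for com, mem, dm, msu, eat in itertools.product(
            (0, 1), (0, 1), range(4), range(4), ADL_CODES
        ):
            a = make_assessment(
                comatose=com,
                short_term_memory_problem=mem,
                decision_making=dm,
                making_self_understood=msu,
                adl_eating=eat,
            )
            got = cps_score(a)
            assert 0 <= got <= 6
            assert got == cps_oracle(com, mem, dm, msu, eat), (com, mem, dm, msu, eat)

    def test_missing_cognition_item_is_non_computable(self):
        a = make_assessment()
        a.items["decision_making"] = None
        with pytest.raises(NonComputable) as exc:
            cps_score(a)
        assert "decision_making" in str(exc.value)


class TestAdlHierarchy:
    def test_independent_and_total_dependence_bounds(self):
        assert adl_hierarchy(make_assessment()) == 0
        a = make_assessment(
            adl_hygiene=6, adl_toilet_use=6, adl_locomotion=6, adl_eating=6
        )
        assert adl_hierarchy(a) == 6

    def test_agrees_with_lookup_oracle_exhaustively(self):
        """All 8^4 item combinations match the published hierarchy grid."""
        for hyg, toi, loc, eat in itertools.product(ADL_CODES, repeat=4):
            a = make_assessment(
                adl_hygiene=hyg, adl_toilet_use=toi, adl_locomotion=loc, adl_eating=eat
            )
            got = adl_hierarchy(a)
            assert 0 <= got <= 6
            assert got == adl_hierarchy_oracle(hyg, toi, loc, eat), (hyg, toi, loc, eat)

    def test_monotone_in_every_item(self):
        """Raising any single item's dependence never lowers the score."""
        items = ("adl_hygiene", "adl_toilet_use", "adl_locomotion", "adl_eating")
        for combo in itertools.product(range(7), repeat=4):
            base = adl_hierarchy(make_assessment(**dict(zip(items, combo))))
            for i, item in enumerate(items):
                if combo[i] < 6:
                    raised = dict(zip(items, combo))
                    raised[item] = combo[i] + 1
                    assert adl_hierarchy(make_assessment(**raised)) >= base

    def test_missing_item_is_non_computable(self):
        a = make_assessment()
        del a.items["adl_locomotion"]
        with pytest.raises(NonComputable):
            adl_hierarchy(a)


class TestAdlDecline:
    def test_no_change_is_not_decline(self):
        a = make_assessment()
        assert adl_decline(a, a) is False

    def test_worsening_is_decline_improvement_is_not(self):
        pre = make_assessment()
        adm = make_assessment(adl_hygiene=4)  # hierarchy 0 -> 3
        assert adl_decline(pre, adm) is True
        assert adl_decline(adm, pre) is False


class TestBehavior:
    def test_any_single_flag_triggers(self):
        assert behavior_disturbance(make_assessment()) is False
        assert behavior_disturbance(make_assessment(resists_care=1)) is True
        a = make_assessment(
            verbally_abusive=1, physically_abusive=1, socially_inappropriate=1, resists_care=1
        )
        assert behavior_disturbance(a) is True


class TestInstitutionalRisk:
    def test_activation_iff_three_or_more_over_all_combinations(self):
        """active <=> count >= 3, exhaustively over all 2^8 category sets."""
        for combo in itertools.product((False, True), repeat=N_RISK_CATEGORIES):
            r = institutional_risk_from_categories(combo)
            assert r.count == sum(combo)
            assert r.active == (r.count >= 3)

    def test_category_count_is_exactly_eight(self):
        a = make_assessment()
        cats = risk_categories(a, declined=False)
        assert len(cats) == N_RISK_CATEGORIES

    def test_homebound_polarity(self):
        """The going-out risk fires when the person does NOT go out."""
        home = make_assessment(goes_out=0)
        out = make_assessment(goes_out=1)
        assert risk_categories(home, declined=False)[1] is True
        assert risk_categories(out, declined=False)[1] is False

    def test_risk_diagnosis_is_any_of_four_diseases(self):
        for disease in ("dementia", "alzheimers", "multiple_sclerosis", "head_trauma"):
            a = make_assessment(**{disease: 1})
            assert risk_categories(a, declined=False)[3] is True

    def test_wrong_category_count_rejected(self):
        with pytest.raises(ValueError):
            institutional_risk_from_categories([True] * 7)


class TestGeriatricScreener:
    def test_all_negative_scores_zero(self):
        assert geriatric_screener(make_assessment()) == 0

    def test_stamina_like_item_has_no_effect(self):
        a = make_assessment()
        b = make_assessment()
        b.items["stamina"] = 3  # no acute-care counterpart: structurally ignored
        assert geriatric_screener(a) == geriatric_screener(b)

    def test_monotone_over_flag_grid(self):
        """Subscore is non-decreasing as screener flags switch on (exhaustive)."""
        flags = SCREENER_FLAG_ITEMS + ("short_term_memory_problem",)
        for combo in itertools.product((0, 1), repeat=len(flags)):
            score = geriatric_screener(make_assessment(**dict(zip(flags, combo))))
            assert score == sum(combo)
            for i, f in enumerate(flags):
                if combo[i] == 0:
                    raised = dict(zip(flags, combo))
                    raised[f] = 1
                    assert geriatric_screener(make_assessment(**raised)) >= score


def test_scale_operations_are_pure():
    """Same input -> same output; the assessment is not mutated."""
    a = make_assessment(adl_hygiene=3, decision_making=2, short_term_memory_problem=1)
    snapshot = dict(a.items)
    first = (cps_score(a), adl_hierarchy(a), geriatric_screener(a))
    second = (cps_score(a), adl_hierarchy(a), geriatric_screener(a))
    assert first == second
    assert a.items == snapshot
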