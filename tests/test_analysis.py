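"""Attended-feature inference, stickiness scoring, and the statistics."""

from fractions import Fraction
from math import comb, isclose

import numpy as np
import pytest

from dualconcept.analysis import (
    TRIAL6_PREVIOUS,
    classify_h1,
    classify_transition,
    h1_test,
    infer_attended,
    mdl_bias_tally,
    predicted_selection,
    stickiness_null,
    stickiness_score,
    time_ratio_test,
    trial6_candidates,
)
from dualconcept.logic import parse_formula
from dualconcept.stimuli import ParticipantRecord, TrialResponse


def quads_of(ids, trial6):
    """(p3,p4,p7,p8) coordinates of selected trial-6 elements."""
    return {
        (v[0], v[1], v[4], v[5])
        for v in (trial6.valuation_of(e) for e in ids)
    }


class TestPredictedSelection:
    def test_p7p8_rule_selects_four_elements(self, trial6):
        sel = predicted_selection(parse_formula("~p7 & ~p8"), trial6)
        assert quads_of(sel, trial6) == {(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 0, 0)}

    def test_three_feature_rule_selects_two(self, trial6):
        sel = predicted_selection(parse_formula("p3 & ~p7 & ~p8"), trial6)
        assert quads_of(sel, trial6) == {(1, 0, 0, 0), (1, 1, 0, 0)}

    def test_consensus_element_in_every_candidate(self, trial6):
        for _, rule in trial6_candidates():
            assert (1, 1, 0, 0) in quads_of(predicted_selection(rule, trial6), trial6)

    def test_rule_outside_context_rejected(self, trial6):
        with pytest.raises(ValueError):
            predicted_selection(parse_formula("p1 & p2"), trial6)


class TestTrial6Candidates:
    def test_seven_candidates_with_distinct_predictions(self, trial6):
        cands = trial6_candidates()
        assert len(cands) == 7
        preds = [predicted_selection(rule, trial6) for _, rule in cands]
        assert len(set(preds)) == 7

    def test_each_rule_minimal_over_its_subset(self):
        from dualconcept.logic import formula_vars
        from dualconcept.mdl import is_minimal

        for sub, rule in trial6_candidates():
            assert formula_vars(rule) == sub
            assert is_minimal(rule)


class TestInferAttended:
    def test_inference_inverts_prediction_for_every_candidate(self, plans):
        for plan in plans.values():
            for t in plan.trials:
                from dualconcept.analysis import default_candidates

                for sub, rule in default_candidates(t):
                    inf = infer_attended(predicted_selection(rule, t), t)
                    assert inf.verdict == "matched"
                    assert inf.attended == frozenset(sub)

    def test_singleton_consensus_selection(self, trial6):
        target = next(
            e for e in trial6.gen_shown_ids
            if quads_of({e}, trial6) == {(1, 1, 0, 0)}
        )
        inf = infer_attended({target}, trial6)
        assert inf.verdict == "matched"
        assert inf.attended == frozenset({3, 4, 7, 8})

    def test_empty_selection_has_no_rationale(self, trial6):
        assert infer_attended(set(), trial6).verdict == "no_rationale"

    def test_one_away_tolerance(self, trial6):
        full = predicted_selection(parse_formula("~p7 & ~p8"), trial6)
        dropped = full - {sorted(full)[0]}
        assert infer_attended(dropped, trial6).verdict == "no_rationale"
        near = infer_attended(dropped, trial6, tolerance="one_away")
        # distance-1 neighbours may be ambiguous; accept a unique hit only
        if near.verdict == "one_away":
            assert near.attended == frozenset({7, 8})


class TestStickiness:
    @pytest.mark.parametrize(
        "attended,score",
        [
            ({7, 8}, Fraction(1)),
            ({3, 7, 8}, Fraction(2, 3)),
            ({4, 7, 8}, Fraction(2, 3)),
            ({3, 4, 7, 8}, Fraction(1, 2)),
            ({3, 4, 7}, Fraction(1, 3)),
            ({3, 4, 8}, Fraction(1, 3)),
            ({3, 4}, Fraction(0)),
        ],
    )
    def test_printed_scores_reproduced(self, attended, score):
        assert stickiness_score(attended, TRIAL6_PREVIOUS) == score

    def test_empty_attended_rejected(self):
        with pytest.raises(ValueError):
            stickiness_score(set(), {7, 8})

    def test_null_mean_converges_to_half(self):
        null = stickiness_null(89, 10_000, seed=0)
        scores = [float(stickiness_score(s, TRIAL6_PREVIOUS)) for s, _ in trial6_candidates()]
        sd = np.std(scores)
        se = sd / np.sqrt(89 * 10_000)
        assert abs(null.means.mean() - 0.5) < 3 * se

    def test_maximal_observed_mean_gets_upper_bound_p(self):
        null = stickiness_null(89, 1000, seed=0, observed_mean=1.0)
        assert null.p_value <= 1 / 1000

    def test_deterministic_given_seed(self):
        a = stickiness_null(10, 500, seed=3, observed_mean=0.6)
        b = stickiness_null(10, 500, seed=3, observed_mean=0.6)
        assert a.p_value == b.p_value


class TestH1:
    def test_exact_conjunction_side_selection(self, trial1):
        conj_side = trial1.ids_of(trial1.gen_side2)  # p3&p4 only
        disj_side = trial1.ids_of(trial1.gen_side1)
        assert classify_h1(conj_side, trial1) == "conjunction"
        assert classify_h1(disj_side, trial1) == "disjunction"
        assert classify_h1(set(list(conj_side)[:1]) | set(list(disj_side)[:1]), trial1) == "neither"

    def test_negative_interpretation_swaps_labels(self, trial1):
        disj_side = trial1.ids_of(trial1.gen_side1)
        assert classify_h1(disj_side, trial1, negative_flag=True) == "conjunction"

    def test_binomial_tail_equals_direct_summation(self):
        for n_conj, n_disj in [(77, 11), (10, 10), (0, 5), (5, 0), (60, 40)]:
            n = n_conj + n_disj
            oracle = sum(comb(n, i) for i in range(n_conj, n + 1)) / 2**n
            assert isclose(h1_test(n_conj, n_disj, 0), oracle, rel_tol=1e-12)

    def test_vacuous_counts_give_p_one(self):
        assert h1_test(0, 0, 10) == 1.0

    def test_tail_monotone_in_conjunction_count(self):
        assert h1_test(88, 0, 12) < h1_test(77, 11, 12)

    def test_random_subset_null_is_extreme_for_real_counts(self, trial1):
        p = h1_test(77, 11, 12, null="random_subset_sim", seed=0, trial=trial1, n_sims=2000)
        assert p <= 1 / 2000


class TestTransitions:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            ("p3 & p4", "~p1 & p2", "kept_operator"),
            ("p1 | p2", "p3 | ~p4", "kept_operator"),
            ("p3 & p4", "p3 | ~p4", "kept_features"),
            ("p3 & p4", "p3 & p4", "kept_both"),
            ("p1 | p2", "~p3 & p4", "kept_neither"),
        ],
    )
    def test_classes(self, r1, r2, expected):
        assert classify_transition(parse_formula(r1), parse_formula(r2)) == expected

    def test_unrecovered_rule_unclassifiable(self):
        assert classify_transition(None, parse_formula("p1 & p2")) == "unclassifiable"


def _time_record(pid, group, t4, t5):
    responses = {
        i: TrialResponse(frozenset(), {4: t4, 5: t5}.get(i, 10.0), 1) for i in range(1, 7)
    }
    return ParticipantRecord(id=pid, group=group, responses=responses)


class TestTimeRatio:
    def test_outlier_excluded(self):
        records = [
            _time_record("out", "X", 100.0, 10.0),
            _time_record("x1", "X", 12.0, 10.0),
            _time_record("x2", "X", 14.0, 10.0),
            _time_record("y1", "Y", 8.0, 10.0),
            _time_record("y2", "Y", 9.0, 10.0),
        ]
        result = time_ratio_test(records)
        assert result.excluded == ("out",)
        assert result.df == 2

    def test_t_and_d_match_hand_computation(self):
        # X ratios {1.2,1.4,1.3}, Y {0.8,0.9,1.0}: pooled sd 0.1,
        # t = 0.4/(0.1*sqrt(2/3)) = 4.898979..., d = 4.0
        records = [
            _time_record("x1", "X", 12.0, 10.0),
            _time_record("x2", "X", 14.0, 10.0),
            _time_record("x3", "X", 13.0, 10.0),
            _time_record("y1", "Y", 8.0, 10.0),
            _time_record("y2", "Y", 9.0, 10.0),
            _time_record("y3", "Y", 10.0, 10.0),
        ]
        result = time_ratio_test(records)
        assert isclose(result.t, 4.898979485566356, rel_tol=1e-9)
        assert isclose(result.d, 4.0, rel_tol=1e-9)
        assert result.df == 4

    def test_identical_distributions_give_zero_effect(self):
        records = [
            _time_record(f"x{i}", "X", t, 10.0) for i, t in enumerate([11.0, 12.0, 13.0])
        ] + [
            _time_record(f"y{i}", "Y", t, 10.0) for i, t in enumerate([11.0, 12.0, 13.0])
        ]
        result = time_ratio_test(records)
        assert result.d == 0.0
        assert abs(result.t) < 1e-12

    def test_emptied_group_rejected(self):
        records = [
            _time_record("x1", "X", 12.0, 10.0),
            _time_record("x2", "X", 13.0, 10.0),
            _time_record("y1", "Y", 100.0, 10.0),
            _time_record("y2", "Y", 90.0, 10.0),
        ]
        with pytest.raises(ValueError):
            time_ratio_test(records)


class TestMdlBiasTally:
    def test_pure_short_rule_cohort(self, plan_x):
        records = []
        for pid in ("a", "b"):
            responses = {}
            for t in plan_x.trials:
                sel = (
                    predicted_selection(t.phi1, t)
                    if t.index in (3, 4, 5)
                    else frozenset()
                )
                responses[t.index] = TrialResponse(sel, 10.0, 1)
            records.append(ParticipantRecord(pid, "X", responses))
        counts = mdl_bias_tally(records, plan_x)
        assert counts == {
            "short_rule_consistent": 6,
            "long_rule_consistent": 0,
            "neither": 0,
        }

    def test_long_rule_response_counted(self, plan_x):
        t3 = plan_x.trial(3)
        responses = {
            t.index: TrialResponse(
                predicted_selection(t.phi2, t) if t.index == 3 else frozenset(), 10.0, 1
            )
            for t in plan_x.trials
        }
        counts = mdl_bias_tally([ParticipantRecord("a", "X", responses)], plan_x)
        assert counts["long_rule_consistent"] == 1
        assert counts["neither"] == 2
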