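"""Classification rules, fold ordering, success and difficulty statistics."""

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from foldswitch.assessment import (
    FOLD1,
    FOLD2,
    OTHER,
    ModelAssessment,
    assign_fold_order,
    classify_model,
    false_positive_rate,
    label_difficulty,
    match_training_roster,
    pair_success,
    success_rate,
    summarize_pair,
)
from foldswitch.synthetic import EnsembleSpec, make_ensemble, perturb


def _assessment(label, plddt=None, mid="m"):
    tm1 = 0.8 if label == FOLD1 else 0.2
    tm2 = 0.8 if label == FOLD2 else 0.2
    return ModelAssessment(mid, tm1, tm2, 1.0, 1.0, label, mean_plddt=plddt,
                           confidence_fraction=None)


class TestClassifyModel:
    @pytest.mark.parametrize("tm1,tm2,expected", [
        (0.7, 0.3, FOLD1),          # above threshold vs one fold only
        (0.3, 0.7, FOLD2),
        (0.65, 0.72, FOLD2),        # both above: larger TM wins
        (0.72, 0.65, FOLD1),
        (0.60, 0.60, OTHER),        # threshold itself is not success
        (0.60, 0.2, OTHER),
        (0.1, 0.2, OTHER),
    ])
    def test_threshold_and_tie_rules(self, tm1, tm2, expected):
        assert classify_model(tm1, tm2) == expected

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_total_function(self, tm1, tm2):
        assert classify_model(tm1, tm2) in {FOLD1, FOLD2, OTHER}

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_swap_symmetry(self, tm1, tm2):
        """Relabeling the fold order swaps FOLD1/FOLD2 and fixes OTHER
        (away from the exact tm1 == tm2 tie, which is broken to Fold1)."""
        assume(tm1 != tm2)
        swap = {FOLD1: FOLD2, FOLD2: FOLD1, OTHER: OTHER}
        assert classify_model(tm2, tm1) == swap[classify_model(tm1, tm2)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_model(1.2, 0.5)


class TestPairSuccess:
    @pytest.mark.parametrize("labels,expected", [
        ([FOLD1, OTHER, FOLD1], (True, False, False)),
        ([FOLD1, FOLD2], (True, True, True)),
        ([OTHER], (False, False, False)),
    ])
    def test_n_ij_rule(self, labels, expected):
        assessments = [_assessment(l, mid=str(i)) for i, l in enumerate(labels)]
        assert pair_success(assessments) == expected

    def test_union_monotonicity(self, toy_pair):
        """Pooling ensembles across methods never lowers the success rate."""
        a = [_assessment(FOLD1)]
        b = [_assessment(FOLD2)]
        s_a, s_b = pair_success(a)[2], pair_success(b)[2]
        s_union = pair_success(a + b)[2]
        assert s_union >= max(s_a, s_b)


class TestSuccessRate:
    def test_fraction(self):
        from foldswitch.assessment import PairSummary

        summaries = [
            PairSummary(str(i), "A", {}, True, True, i < 32, "EASY", None, 1)
            for i in range(92)
        ]
        assert success_rate(summaries) == pytest.approx(32 / 92)
        assert success_rate(summaries) == pytest.approx(0.3478, abs=1e-4)

    def test_extremes(self):
        from foldswitch.assessment import PairSummary

        none = [PairSummary("x", "A", {}, False, False, False, "EASY", None, 1)]
        allw = [PairSummary("x", "A", {}, True, True, True, "EASY", None, 1)]
        assert success_rate(none) == 0.0
        assert success_rate(allw) == 1.0


class TestLabelDifficulty:
    @pytest.mark.parametrize("wrmsd,fstm,amyloid,expected", [
        (12.0, 0.7, False, "COMPLEX"),   # large whole-structure change
        (4.0, 0.45, False, "COMPLEX"),   # dissimilar fold-switching region
        (4.0, 0.7, False, "EASY"),
        (4.0, 0.7, True, "COMPLEX"),     # amyloid / domain swap route
        (10.0, 0.5, False, "EASY"),      # both boundaries are exclusive
    ])
    def test_rules(self, wrmsd, fstm, amyloid, expected):
        assert label_difficulty(wrmsd, fstm, amyloid) == expected


class TestFalsePositiveRate:
    def test_confident_other_fraction(self):
        a = [
            _assessment(OTHER, 80, "1"), _assessment(OTHER, 75, "2"),
            _assessment(FOLD1, 90, "3"), _assessment(FOLD2, 71, "4"),
            _assessment(OTHER, 50, "5"),  # not confident: ignored
        ]
        assert false_positive_rate(a) == pytest.approx(0.5)

    def test_absent_without_confident_models(self):
        assert false_positive_rate([_assessment(OTHER, 69.9)]) is None

    def test_zero_when_all_confident_correct(self):
        a = [_assessment(FOLD1, 85, str(i)) for i in range(3)]
        assert false_positive_rate(a) == 0.0


class TestAssignFoldOrder:
    def test_unanimous_baseline(self, toy_pair):
        baseline = [perturb(toy_pair.ref_A, 0.5, seed=s, model_id=f"b{s}")
                    for s in range(5)]
        order, tiebreak = assign_fold_order(baseline, toy_pair)
        assert order == "A" and not tiebreak

    def test_majority_3_of_5(self, toy_pair):
        baseline = [perturb(toy_pair.ref_B, 0.5, seed=s, model_id=f"b{s}")
                    for s in range(3)]
        baseline += [perturb(toy_pair.ref_A, 0.5, seed=s, model_id=f"a{s}")
                     for s in range(2)]
        order, _ = assign_fold_order(baseline, toy_pair)
        assert order == "B"

    def test_even_tie_falls_back_to_mean(self, toy_pair):
        baseline = [perturb(toy_pair.ref_A, 0.3, seed=1, model_id="a"),
                    perturb(toy_pair.ref_B, 1.2, seed=2, model_id="b")]
        order, tiebreak = assign_fold_order(baseline, toy_pair)
        assert tiebreak
        assert order == "A"  # the less-perturbed side has the larger mean TM

    def test_no_baseline_instructs_configuration(self, toy_pair):
        with pytest.raises(ValueError, match="fold_order"):
            assign_fold_order([], toy_pair)


class TestTrainingRoster:
    def test_matching_rules(self, tmp_path):
        roster = tmp_path / "duplicate_pdb_chains.txt"
        roster.write_text("2oug_C 1abc_A\n3xyz_B\n")
        flags = match_training_roster(
            ["2oug_C", "9zzz_A", "2OUG_C", "2oug_c"], roster
        )
        # pdb id case-insensitive, chain case-sensitive
        assert flags == [True, False, True, False]

    def test_unreadable_roster(self, tmp_path):
        with pytest.raises(OSError):
            match_training_roster(["1abc_A"], tmp_path / "missing.txt")


class TestSummarizePair:
    def test_counts_conserved_and_difficulty(self, toy_pair):
        models, labels = make_ensemble(
            toy_pair, EnsembleSpec(n_models=12, weights=(0.5, 0.25, 0.25), seed=3)
        )
        from foldswitch.pipeline import assess_ensemble

        assessments, summary, _ = assess_ensemble(toy_pair, models, fold_order="A")
        assert sum(summary.counts.values()) == 12
        # H->E rebuild guarantees a Complex-grade structural difference
        assert summary.difficulty == "COMPLEX"
        assert summary.success_overall == (
            summary.counts[FOLD1] >= 1 and summary.counts[FOLD2] >= 1
        )
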