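"""Penalty score and exhaustive best-subset selection."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutriscreen import (
    CohortConfig,
    PenaltyWeights,
    SeverityConfusion,
    confusion,
    enumerate_models,
    generate_cohort,
    metrics,
    penalty_score,
    selection_report,
)
from nutriscreen.cohort import PatientRecord
from nutriscreen.engine import DAILY_ELEMENTS, ScreenElementVector
from nutriscreen.fixtures import SEVERITY_LEVELS


def _conf(pos, neg):
    return SeverityConfusion(
        dict(zip(SEVERITY_LEVELS, pos)), dict(zip(SEVERITY_LEVELS, neg))
    )


def oracle_penalty(pos, neg, w, mode):
    """Independently coded weighted sum over raw counts."""
    fp_none, fp_mild = pos[0], pos[1]
    fn_mild, fn_mod, fn_sev = neg[1], neg[2], neg[3]
    if mode == "any_malnutrition":
        return w[0] * fn_mild + w[1] * fn_mod + w[2] * fn_sev + w[3] * fp_none
    return w[1] * fn_mod + w[2] * fn_sev + w[3] * (fp_none + fp_mild)


class TestPenaltyScore:
    def test_perfect_prediction_scores_zero(self):
        conf = _conf((0, 5, 4, 3), (20, 0, 0, 0))
        assert penalty_score(conf) == 0.0
        assert penalty_score(conf, mode="moderate_severe") == pytest.approx(
            0.2 * 5  # flagged mild patients now charge the FP weight
        )

    def test_stated_weights_arithmetic(self):
        # one missed case of each severity plus ten false positives
        conf = _conf((10, 0, 0, 0), (0, 1, 1, 1))
        assert penalty_score(conf) == pytest.approx(1 + 3 + 5 + 10 * 0.2)

    def test_unit_weights_degenerate_to_error_count(self):
        conf = _conf((7, 2, 1, 0), (30, 4, 3, 2))
        unit = PenaltyWeights(1, 1, 1, 1)
        assert penalty_score(conf, unit) == 7 + 4 + 3 + 2

    def test_thousand_random_confusions_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            pos = rng.integers(0, 50, size=4)
            neg = rng.integers(0, 50, size=4)
            w = rng.uniform(0, 5, size=4)
            conf = _conf(pos, neg)
            weights = PenaltyWeights(w[0], w[1], w[2], w[3])
            for mode in ("any_malnutrition", "moderate_severe"):
                assert penalty_score(conf, weights, mode) == pytest.approx(
                    oracle_penalty(pos, neg, w, mode), abs=1e-12
                )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            PenaltyWeights(miss_mild=-1)


def brute_force_selection(cohort, vocab, weights, mode):
    """Independent exhaustive loop: numpy columns, bitmask subsets."""
    assessed = [r for r in cohort if r.assessed]
    X = np.array([[r.elements[e] for e in vocab] for r in assessed], bool)
    sev = np.array([r.severity for r in assessed])
    scores = {}
    for mask in range(1, 2 ** len(vocab)):
        idx = [j for j in range(len(vocab)) if mask >> j & 1]
        pred = X[:, idx].any(axis=1)
        fn = {s: int(((~pred) & (sev == s)).sum()) for s in SEVERITY_LEVELS}
        fp = {s: int((pred & (sev == s)).sum()) for s in SEVERITY_LEVELS}
        if mode == "any_malnutrition":
            score = (weights.miss_mild * fn["mild"]
                     + weights.miss_moderate * fn["moderate"]
                     + weights.miss_severe * fn["severe"]
                     + weights.false_positive * fp["none"])
        else:
            score = (weights.miss_moderate * fn["moderate"]
                     + weights.miss_severe * fn["severe"]
                     + weights.false_positive * (fp["none"] + fp["mild"]))
        scores[frozenset(vocab[j] for j in idx)] = score
    return scores


def _make_patient(i, severity, **elements):
    return PatientRecord(
        patient_id=f"p{i}", age_years=5.0, corrected_age_years=5.0,
        severity=severity, assessed=True,
        elements=ScreenElementVector(**elements),
    )


class TestEnumerateModels:
    @pytest.mark.parametrize("mode", ["any_malnutrition", "moderate_severe"])
    def test_matches_independent_brute_force(self, mode):
        cohort = generate_cohort(CohortConfig(n_unassessed=0, seed=21))
        weights = PenaltyWeights()
        result = enumerate_models(cohort, weights=weights, mode=mode)
        oracle = brute_force_selection(cohort, result.vocabulary, weights, mode)
        assert len(result.all_models) == 2 ** len(result.vocabulary) - 1
        for model in result.all_models:
            assert model.score == pytest.approx(
                oracle[frozenset(model.elements)], abs=1e-12
            )
        for size, best_models in result.per_size_best.items():
            size_scores = {s: v for s, v in oracle.items() if len(s) == size}
            best = min(size_scores.values())
            expected = {s for s, v in size_scores.items()
                        if v <= best + 1e-9}
            assert {frozenset(m.elements) for m in best_models} == expected
        global_min = min(oracle.values())
        assert {frozenset(m.elements) for m in result.global_best} == {
            s for s, v in oracle.items() if v <= global_min + 1e-9
        }

    def test_oracle_element_wins_with_zero_score(self):
        cohort = [
            _make_patient(i, sev, pnst_positive=(sev != "none"),
                          enteral_nutrition=(i % 2 == 0))
            for i, sev in enumerate(
                ["none"] * 6 + ["mild", "mild", "moderate", "severe"]
            )
        ]
        result = enumerate_models(
            cohort, vocabulary=["pnst_positive", "enteral_nutrition"]
        )
        assert len(result.global_best) == 1
        assert result.global_best[0].elements == ("pnst_positive",)
        assert result.global_best[0].score == 0.0

    def test_identical_columns_tie_and_both_reported(self):
        cohort = [
            _make_patient(i, sev, enteral_nutrition=flag, intubation=flag)
            for i, (sev, flag) in enumerate(
                [("none", False)] * 5 + [("mild", True)] * 3
                + [("moderate", False), ("severe", True)]
            )
        ]
        result = enumerate_models(
            cohort, vocabulary=["enteral_nutrition", "intubation"]
        )
        singles = result.per_size_best[1]
        assert len(singles) == 2
        assert singles[0].score == singles[1].score
        # lexicographic tie order is deterministic
        assert [m.elements for m in singles] == [
            ("enteral_nutrition",), ("intubation",)
        ]

    def test_invariant_to_vocabulary_order(self, assessed_only_cohort):
        vocab = list(DAILY_ELEMENTS)
        a = enumerate_models(assessed_only_cohort, vocabulary=vocab)
        b = enumerate_models(assessed_only_cohort, vocabulary=vocab[::-1])
        assert a.per_size_best == b.per_size_best
        assert a.global_best == b.global_best

    def test_manual_enumeration_tiny_cohort(self):
        # 6 patients, 2 elements: every subset checked by hand
        cohort = [
            _make_patient(0, "none"),
            _make_patient(1, "none", enteral_nutrition=True),
            _make_patient(2, "mild", enteral_nutrition=True),
            _make_patient(3, "mild", pnst_positive=True),
            _make_patient(4, "moderate", enteral_nutrition=True,
                          pnst_positive=True),
            _make_patient(5, "severe"),
        ]
        result = enumerate_models(
            cohort, vocabulary=["enteral_nutrition", "pnst_positive"]
        )
        by_subset = {m.elements: m.score for m in result.all_models}
        # EN: misses mild(p3)=1, severe(p5)=5, FP none(p1)=0.2 -> 6.2
        assert by_subset[("enteral_nutrition",)] == pytest.approx(6.2)
        # PNST: misses mild(p2)=1, severe(p5)=5 -> 6.0
        assert by_subset[("pnst_positive",)] == pytest.approx(6.0)
        # both: misses severe(p5)=5, FP none(p1)=0.2 -> 5.2
        assert by_subset[("enteral_nutrition", "pnst_positive")] == (
            pytest.approx(5.2)
        )
        assert result.global_best[0].elements == (
            "enteral_nutrition", "pnst_positive",
        )

    def test_or_monotonicity_across_nested_subsets(self, assessed_only_cohort):
        result = enumerate_models(assessed_only_cohort)
        by_subset = {frozenset(m.elements): m for m in result.all_models}
        for sub, model in by_subset.items():
            for extra in set(result.vocabulary) - set(sub):
                bigger = by_subset[sub | {extra}]
                assert bigger.metrics.sensitivity >= model.metrics.sensitivity
                assert bigger.metrics.specificity <= model.metrics.specificity

    def test_vocabulary_above_exhaustive_cap_rejected(self, assessed_only_cohort):
        fake_vocab = [f"e{i}" for i in range(21)]
        with pytest.raises(ValueError, match="exhaustive cap"):
            enumerate_models(assessed_only_cohort, vocabulary=fake_vocab)

    def test_no_assessed_patients_rejected(self, default_cohort):
        unassessed = [r for r in default_cohort if not r.assessed]
        with pytest.raises(ValueError, match="assessed"):
            enumerate_models(unassessed)


class TestSelectionReport:
    def test_row_schema_and_formatting(self, assessed_only_cohort):
        result = enumerate_models(assessed_only_cohort)
        rows = selection_report(result)
        assert list(rows[0]) == ["N", "Score", "Screening Variables",
                                 "Sensitivity", "Specificity", "PPV", "NPV"]
        assert len(rows) >= len(result.per_size_best)
        for row in rows:
            assert "." in row["Score"] and len(row["Score"].split(".")[1]) == 1

    def test_metrics_recomputable_from_stored_confusion(self,
                                                        assessed_only_cohort):
        result = enumerate_models(assessed_only_cohort)
        for models in result.per_size_best.values():
            for model in models:
                again = metrics(model.confusion, result.mode)
                assert again == model.metrics
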