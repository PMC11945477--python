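"""Accuracy statistic, combination sweep, ranking and dispersion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgid import (
    AccuracyReport,
    ClassProbabilities,
    SubjectFeatures,
    TrainConfig,
    accuracy_rate,
    correctness_indicator,
    enumerate_patterns,
    probability_bar_report,
    rank_patterns,
    spectrum_dispersion,
    sweep_combinations,
)
from bcgid.evaluate import SweepResult, pattern_seed, run_pattern

LABELS = ("M0", "M1", "M2", "M3", "M4")


def make_prediction(p_own, true_label="M0", labels=LABELS):
    probs = np.full(5, (1 - p_own) / 4)
    probs[labels.index(true_label)] = p_own
    return ClassProbabilities(probs, labels, true_label=true_label)


class TestCorrectnessIndicator:
    @pytest.mark.parametrize("p,expected", [(0.5, 1), (0.4999, 0), (1.0, 1), (0.0, 0)])
    def test_boundary_inclusive_threshold(self, p, expected):
        assert correctness_indicator(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            correctness_indicator(p)

    def test_half_threshold_implies_argmax_but_not_conversely(self):
        # P >= 0.5 forces the own class to be the argmax; an argmax win at
        # 0.4 still counts as incorrect under the threshold rule.
        winner = make_prediction(0.55)
        assert correctness_indicator(winner.own_probability) == 1
        assert int(np.argmax(winner.probs)) == 0
        plurality = ClassProbabilities(
            np.array([0.4, 0.3, 0.1, 0.1, 0.1]), LABELS, true_label="M0"
        )
        assert int(np.argmax(plurality.probs)) == 0
        assert correctness_indicator(plurality.own_probability) == 0


class TestAccuracyRate:
    def test_hand_worked_example(self):
        preds = [make_prediction(p) for p in (0.9, 0.6, 0.5, 0.3)]
        report = accuracy_rate(preds)
        assert report.per_class["M0"]["rate"] == pytest.approx(0.75)
        assert report.per_class["M0"]["m_k"] == 4
        assert report.per_class["M0"]["correct"] == 3

    def test_all_confident_gives_rate_one(self):
        report = accuracy_rate([make_prediction(0.8, t) for t in LABELS for _ in range(3)])
        assert all(v["rate"] == 1.0 for v in report.per_class.values())

    def test_absent_class_not_reported_as_zero(self):
        report = accuracy_rate([make_prediction(0.9, "M1")])
        assert "M0" not in report.per_class

    def test_unknown_label_rejected(self):
        bad = ClassProbabilities(np.full(5, 0.2), LABELS, true_label="Mx")
        with pytest.raises(ValueError):
            accuracy_rate([bad])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        preds = []
        for _ in range(rng.integers(5, 40)):
            probs = rng.dirichlet(np.ones(5))
            true = LABELS[rng.integers(0, 5)]
            preds.append(ClassProbabilities(probs, LABELS, true_label=true))
        report = accuracy_rate(preds)
        # independent recount, straight from the definition
        for cls in {p.true_label for p in preds}:
            mine = [p for p in preds if p.true_label == cls]
            n_correct = sum(
                1 for p in mine if p.probs[LABELS.index(cls)] >= 0.5
            )
            assert report.per_class[cls]["rate"] == n_correct / len(mine)


class TestPatternEnumeration:
    @given(n=st.integers(2, 10), k=st.integers(2, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cardinality_is_n_choose_k(self, n, k):
        if k > n:
            return
        ids = [f"M{i}" for i in range(n)]
        assert len(enumerate_patterns(ids, k)) == math.comb(n, k)

    def test_patterns_sorted_and_unique(self):
        pats = enumerate_patterns([f"M{i}" for i in range(6)], 5)
        assert len(set(pats)) == 6
        assert all(tuple(sorted(p)) == p for p in pats)

    def test_pattern_seed_stable_and_bounded(self):
        s = pattern_seed(7, "02367")
        assert s == pattern_seed(7, "02367")
        assert 0 <= s < 2**31
        assert s != pattern_seed(7, "02368")


def synthetic_features(rng, subjects, n_train=30, n_test=10, blur=0.0):
    """Block-structured separable features; `blur` mixes a subject toward M0."""
    feats = {}
    for i, sid in enumerate(subjects):
        centre = np.zeros(150)
        centre[15 * i : 15 * i + 15] = 1.0
        if blur and i == len(subjects) - 1:
            other = np.zeros(150)
            other[:15] = 1.0
            centre = (1 - blur) * centre + blur * other
        train = np.clip(centre + rng.normal(0, 0.05, (n_train, 150)), 0, 1)
        test = np.clip(centre + rng.normal(0, 0.05, (n_test, 150)), 0, 1)
        feats[sid] = SubjectFeatures(sid, train, test)
    return feats


FAST = dict(epochs=60, learning_rate=0.01)


class TestSweep:
    def test_five_of_five_single_pattern(self, rng):
        feats = synthetic_features(rng, [f"M{i}" for i in range(5)])
        sweep = sweep_combinations(feats, 5, TrainConfig(**FAST), base_seed=3)
        assert sweep.n_patterns == 1
        assert sweep.n_results == 5

    def test_six_choose_five_patterns(self, rng):
        feats = synthetic_features(rng, [f"M{i}" for i in range(6)])
        sweep = sweep_combinations(feats, 5, TrainConfig(**FAST), base_seed=3)
        assert sweep.n_patterns == 6
        ids = {r.pattern_id for r in sweep.reports}
        assert ids == {"01234", "01235", "01245", "01345", "02345", "12345"}

    def test_single_pattern_rerun_reproduces_sweep_report(self, rng):
        feats = synthetic_features(rng, [f"M{i}" for i in range(6)])
        cfg = TrainConfig(**FAST)
        sweep = sweep_combinations(feats, 5, cfg, base_seed=11)
        target = sweep.reports[2]
        members = tuple(sorted(target.per_class))
        standalone, _, _ = run_pattern(feats, members, cfg, base_seed=11)
        assert standalone.pattern_id == target.pattern_id
        assert standalone.per_class == target.per_class

    def test_missing_features_rejected(self, rng):
        feats = synthetic_features(rng, [f"M{i}" for i in range(5)])
        feats["M4"] = SubjectFeatures("M4", feats["M4"].train, np.empty((0, 150)))
        with pytest.raises(ValueError):
            sweep_combinations(feats, 5, TrainConfig(**FAST), base_seed=0)


def fake_report(pid, rate_by_class):
    return AccuracyReport(
        pattern_id=pid,
        per_class={c: {"m_k": 10, "correct": int(10 * r), "rate": r}
                   for c, r in rate_by_class.items()},
    )


class TestRanking:
    def make_sweep(self, rates):
        reports = [fake_report(pid, {"X": r}) for pid, r in rates.items()]
        return SweepResult(reports, base_seed=0, config=TrainConfig())

    def test_single_pattern_best_is_itself(self):
        sweep = self.make_sweep({"01234": 0.8})
        assert rank_patterns(sweep, "best", 1)[0].pattern_id == "01234"

    def test_best_worst_middle_ordering(self):
        sweep = self.make_sweep({"a": 0.5, "b": 0.9, "c": 0.7, "d": 0.6, "e": 0.8})
        assert [r.pattern_id for r in rank_patterns(sweep, "best", 2)] == ["b", "e"]
        assert [r.pattern_id for r in rank_patterns(sweep, "worst", 2)] == ["a", "d"]
        assert [r.pattern_id for r in rank_patterns(sweep, "middle", 3)] == ["e", "c", "d"]

    def test_ranking_is_a_permutation(self):
        rates = {f"p{i}": 0.5 + 0.01 * i for i in range(9)}
        sweep = self.make_sweep(rates)
        ranked = rank_patterns(sweep, "best", 9)
        assert sorted(r.pattern_id for r in ranked) == sorted(rates)

    def test_degraded_subject_sinks_its_patterns(self, rng):
        # One subject blurred toward another: the worst-ranked patterns all
        # contain the degraded subject.
        feats = synthetic_features(rng, [f"M{i}" for i in range(6)], blur=0.7)
        sweep = sweep_combinations(feats, 5, TrainConfig(**FAST), base_seed=5)
        worst = rank_patterns(sweep, "worst", 3)
        assert all("5" in r.pattern_id for r in worst)

    def test_count_larger_than_sweep_rejected(self):
        sweep = self.make_sweep({"01234": 0.8})
        with pytest.raises(ValueError):
            rank_patterns(sweep, "best", 2)


class TestProbabilityBars:
    def test_perfect_group(self):
        preds = [make_prediction(1.0, "M0") for _ in range(5)]
        report = probability_bar_report(preds)
        assert report.rows["M0"][0] == pytest.approx(1.0)
        assert np.allclose(report.rows["M0"][1:], 0.0)

    def test_uniform_predictor(self):
        preds = [
            ClassProbabilities(np.full(5, 0.2), LABELS, true_label="M2")
            for _ in range(4)
        ]
        row = probability_bar_report(preds).rows["M2"]
        assert row[2] == pytest.approx(0.2)
        assert np.allclose(np.delete(row, 2), -0.2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_row_magnitudes_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        preds = [
            ClassProbabilities(rng.dirichlet(np.ones(5)), LABELS,
                               true_label=LABELS[rng.integers(0, 5)])
            for _ in range(20)
        ]
        report = probability_bar_report(preds)
        for row in report.rows.values():
            assert np.abs(row).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            probability_bar_report([])


class TestDispersion:
    def test_identical_spectra_zero(self):
        assert spectrum_dispersion(np.ones((5, 150))) == 0.0

    def test_two_value_closed_form(self):
        assert spectrum_dispersion(np.array([[0.0], [2.0]])) == pytest.approx(1.0)

    def test_reorder_invariance(self, rng):
        X = rng.uniform(0, 1, (10, 150))
        assert spectrum_dispersion(X) == pytest.approx(
            spectrum_dispersion(X[rng.permutation(10)])
        )

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError):
            spectrum_dispersion(np.ones((1, 150)))
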