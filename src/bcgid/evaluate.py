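"""Accuracy statistic, all-combinations sweep, ranking and diagnostics.

A test window is *correctly classified* when the softmax probability
assigned to its own class is at least 0.5 (boundary inclusive) — not by
argmax. The per-class accuracy rate is

    R_k = (1/m_k) * sum_i n_k^i,   n_k^i = 1 if P_k^i >= 0.5 else 0,

over the m_k test windows of class k. The sweep trains one fresh five-class
network for every k-of-n subject combination (all C(10,5) = 252 patterns by
default, hence 252 x 5 = 1260 per-class results), each with its own seed
derived from (base_seed, pattern id) so any single pattern can be re-run
standalone and reproduce its in-sweep report exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .network import LabeledBatch, N_CLASSES, NetworkParameters, TrainConfig, predict, train

__all__ = [
    "ClassProbabilities",
    "AccuracyReport",
    "SweepResult",
    "ProbabilityBarReport",
    "SubjectFeatures",
    "correctness_indicator",
    "accuracy_rate",
    "enumerate_patterns",
    "pattern_seed",
    "run_pattern",
    "sweep_combinations",
    "rank_patterns",
    "probability_bar_report",
    "spectrum_dispersion",
]


@dataclass
class ClassProbabilities:
    """One test window's softmax output with its class order and true label."""

    probs: np.ndarray
    class_labels: tuple[str, ...]
    true_label: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.class_labels = tuple(self.class_labels)
        if self.probs.shape != (len(self.class_labels),):
            raise ValueError("probs length must match class_labels")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def own_probability(self) -> float:
        if self.true_label is None:
            raise ValueError("no true label attached")
        return float(self.probs[self.class_labels.index(self.true_label)])


@dataclass
class AccuracyReport:
    """Per-class test counts, correct counts and rates for one trained pattern."""

    pattern_id: str
    per_class: dict[str, dict[str, float]]  # class -> {m_k, correct, rate}

    @property
    def mean_rate(self) -> float:
        return float(np.mean([v["rate"] for v in self.per_class.values()]))


@dataclass
class SweepResult:
    reports: list[AccuracyReport]
    base_seed: int
    config: TrainConfig

    @property
    def n_patterns(self) -> int:
        return len(self.reports)

    @property
    def n_results(self) -> int:
        return sum(len(r.per_class) for r in self.reports)

    def mean_rates(self) -> dict[str, float]:
        return {r.pattern_id: r.mean_rate for r in self.reports}

    def all_rates(self) -> list[tuple[str, str, float]]:
        return [
            (r.pattern_id, cls, stats["rate"])
            for r in self.reports
            for cls, stats in r.per_class.items()
        ]


@dataclass
class ProbabilityBarReport:
    """Signed mean classification probabilities per true class.

    ``rows[k][j]`` is the mean probability mass that true-class-k test
    windows place on class j, signed positive for j == k (correct) and
    negative otherwise (misclassification mass); magnitudes in a row sum
    to 1.
    """

    class_labels: tuple[str, ...]
    rows: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SubjectFeatures:
    """Normalised train/test feature matrices for one subject."""

    subject_id: str
    train: np.ndarray  # (n_train, 150)
    test: np.ndarray   # (n_test, 150)


def correctness_indicator(p_own: float) -> int:
    """1 iff the own-class probability is at least 0.5 (boundary inclusive)."""
    if not 0.0 <= p_own <= 1.0:
        raise ValueError(f"probability {p_own} outside [0, 1]")
    return 1 if p_own >= 0.5 else 0


def accuracy_rate(predictions: list[ClassProbabilities], pattern_id: str = "") -> AccuracyReport:
    """Per-class rates R_k = sum_i n_k^i / m_k over labelled predictions.

    Classes with no test windows are absent from the report (not rated 0).
    """
    per_class: dict[str, dict[str, float]] = {}
    for pred in predictions:
        if pred.true_label is None or pred.true_label not in pred.class_labels:
            raise ValueError(f"unknown or missing true label {pred.true_label!r}")
        stats = per_class.setdefault(pred.true_label, {"m_k": 0, "correct": 0})
        stats["m_k"] += 1
        stats["correct"] += correctness_indicator(pred.own_probability)
    for stats in per_class.values():
        stats["rate"] = stats["correct"] / stats["m_k"]
    return AccuracyReport(pattern_id=pattern_id, per_class=per_class)


def enumerate_patterns(subject_ids: list[str], k: int) -> list[tuple[str, ...]]:
    """All k-subsets of the sorted subject ids, in lexicographic order."""
    if k < 1 or k > len(subject_ids):
        raise ValueError("k must satisfy 1 <= k <= n")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject ids must be unique")
    return list(combinations(sorted(subject_ids), k))


def pattern_id_of(members: tuple[str, ...]) -> str:
    """Canonical pattern id: sorted member digits, e.g. ('M0','M2') -> '02'.

    Falls back to joining full ids with '+' when ids are not single-suffix.
    """
    suffixes = [m[1:] for m in members]
    if all(s.isdigit() and len(s) == 1 for s in suffixes):
        return "".join(sorted(suffixes))
    return "+".join(sorted(members))


def pattern_seed(base_seed: int, pattern_id: str) -> int:
    """Deterministic per-pattern seed < 2^31 from (base_seed, pattern id)."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(pattern_id.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v


def run_pattern(
    features: dict[str, SubjectFeatures],
    members: tuple[str, ...],
    config: TrainConfig,
    base_seed: int,
) -> tuple[AccuracyReport, list[ClassProbabilities], NetworkParameters]:
    """Train and evaluate one subject combination with its derived seed."""
    labels = tuple(sorted(members))
    pid = pattern_id_of(labels)
    seed = pattern_seed(base_seed, pid)

    X = np.vstack([features[m].train for m in labels])
    Y = np.vstack(
        [
            np.tile(_one_hot(i, N_CLASSES), (len(features[m].train), 1))
            for i, m in enumerate(labels)
        ]
    )
    cfg = TrainConfig(
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        optimizer=config.optimizer,
        seed=seed,
        early_stop_patience=config.early_stop_patience,
        early_stop_min_delta=config.early_stop_min_delta,
    )
    params, _ = train(LabeledBatch(X, Y), cfg, class_labels=labels)

    predictions: list[ClassProbabilities] = []
    for m in labels:
        probs = predict(params, features[m].test)
        predictions.extend(
            ClassProbabilities(row, labels, true_label=m) for row in probs
        )
    return accuracy_rate(predictions, pattern_id=pid), predictions, params


def sweep_combinations(
    features: dict[str, SubjectFeatures],
    k: int = 5,
    config: TrainConfig | None = None,
    base_seed: int = 0,
) -> SweepResult:
    """Train/evaluate every k-subject combination; C(n, k) reports total."""
    if config is None:
        config = TrainConfig()
    if k != N_CLASSES:
        raise ValueError(f"subset size must equal the {N_CLASSES}-class network width")
    ids = sorted(features)
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects, got {len(ids)}")
    for sid, f in features.items():
        if f.train.size == 0 or f.test.size == 0:
            raise ValueError(f"subject {sid} is missing train or test features")
    reports = [
        run_pattern(features, members, config, base_seed)[0]
        for members in enumerate_patterns(ids, k)
    ]
    return SweepResult(reports=reports, base_seed=base_seed, config=config)


def rank_patterns(
    sweep: SweepResult, selector: str, count: int = 3
) -> list[AccuracyReport]:
    """Top/bottom/middle patterns by mean per-class rate.

    Ties are broken lexicographically by pattern id. ``best`` returns the
    highest-rated ``count`` patterns (best first), ``worst`` the lowest
    (worst first), and ``middle`` the ``count`` patterns centred on the
    median rank of the descending ordering.
    """
    if not sweep.reports:
        raise ValueError("sweep is empty")
    if count < 1 or count > len(sweep.reports):
        raise ValueError("count must be between 1 and the number of patterns")
    ordered = sorted(sweep.reports, key=lambda r: (-r.mean_rate, r.pattern_id))
    if selector == "best":
        return ordered[:count]
    if selector == "worst":
        return ordered[::-1][:count]
    if selector == "middle":
        median = (len(ordered) - 1) // 2
        start = min(max(median - count // 2, 0), len(ordered) - count)
        return ordered[start : start + count]
    raise ValueError(f"unknown selector {selector!r}")


def probability_bar_report(
    predictions: list[ClassProbabilities],
) -> ProbabilityBarReport:
    """Signed mean probabilities per true class (own positive, others negative)."""
    groups: dict[str, list[np.ndarray]] = {}
    labels: tuple[str, ...] | None = None
    for pred in predictions:
        if pred.true_label is None:
            raise ValueError("every prediction needs a true label")
        labels = labels or pred.class_labels
        if pred.class_labels != labels:
            raise ValueError("inconsistent class label order across predictions")
        groups.setdefault(pred.true_label, []).append(pred.probs)
    if labels is None:
        raise ValueError("no predictions given")
    report = ProbabilityBarReport(class_labels=labels)
    for cls, rows in groups.items():
        mean = np.mean(rows, axis=0)
        signed = -mean
        signed[labels.index(cls)] = mean[labels.index(cls)]
        report.rows[cls] = signed
    return report


def spectrum_dispersion(spectra: np.ndarray, per_bin: bool = False) -> float:
    """Pooled standard deviation over all bins of all spectra in a set.

    The scalar dispersion diagnostic: one population SD pooled over every
    bin value of every window (``per_bin=True`` instead averages the
    per-bin SDs across windows — an alternative pooling convention).
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need at least 2 spectra (rows)")
    if per_bin:
        return float(np.mean(spectra.std(axis=0)))
    return float(spectra.std())
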