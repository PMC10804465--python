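"""KNN classification of muscle states with leave-one-out cross-validation.

The classifier is deliberately minimal: k nearest neighbours under the
Pearson dissimilarity, majority vote, with fully deterministic tie-breaking
(distance ties by training order, vote ties by the tied class whose nearest
member is closest, then by the fixed class order).  Chance level for the
six-movement design is 1/6 ≈ 16.7%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_core import MOVEMENTS, TrialSet
from .preprocessing import (
    FeatureMask,
    MuscleState,
    end_muscle_state,
    initial_muscle_state,
    pairwise_dissimilarity,
    pearson_dissimilarity,
)


@dataclass
class LabeledStateSet:
    """Parallel lists of muscle states and movement labels for one limb."""

    states: list[MuscleState]
    labels: list[str]
    subject_id: str = ""
    limb: str = ""

    def __post_init__(self) -> None:
        if len(self.states) != len(self.labels):
            raise ValueError("states and labels must be parallel lists")
        unknown = set(self.labels) - set(MOVEMENTS)
        if unknown:
            raise ValueError(f"unknown movement labels {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def classes(self) -> list[str]:
        present = set(self.labels)
        return [m for m in MOVEMENTS if m in present]

    def matrix(self) -> np.ndarray:
        return np.stack([s.values for s in self.states])

    def states_for(self, movement: str) -> list[MuscleState]:
        return [s for s, l in zip(self.states, self.labels) if l == movement]

    @classmethod
    def from_states(cls, states: Iterable[MuscleState], subject_id: str = "",
                    limb: str = "") -> "LabeledStateSet":
        states = list(states)
        return cls(
            states=states,
            labels=[s.movement for s in states],
            subject_id=subject_id or (states[0].subject_id if states else ""),
            limb=limb or (states[0].limb if states else ""),
        )


@dataclass
class ConfusionMatrix:
    """Counts with rows = true movement, columns = predicted movement."""

    counts: np.ndarray
    classes: tuple[str, ...] = MOVEMENTS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n} for {n} classes")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def chance_level(n_classes: int = len(MOVEMENTS)) -> float:
    """Expected accuracy under movement-label randomization: 1 / n_classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be positive")
    return 1.0 / n_classes


def _predict(dists: np.ndarray, labels: Sequence[str], k: int) -> str:
    """Majority vote over the k nearest; deterministic tie-breaking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} training states")
    order = np.argsort(dists, kind="stable")  # distance ties → training order
    nearest = order[:k]
    votes: dict[str, int] = {}
    best_dist: dict[str, float] = {}
    for idx in nearest:
        lab = labels[idx]
        votes[lab] = votes.get(lab, 0) + 1
        if lab not in best_dist:
            best_dist[lab] = float(dists[idx])
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    # vote tie: nearest member wins, then fixed class order
    return min(tied, key=lambda c: (best_dist[c], MOVEMENTS.index(c)))


def knn_classify(query: MuscleState, train: LabeledStateSet, k: int = 1) -> str:
    """Classify one muscle state against a labeled training set."""
    dists = np.array([pearson_dissimilarity(query, s) for s in train.states])
    return _predict(dists, train.labels, k)


def loocv(state_set: LabeledStateSet, k: int = 1) -> ConfusionMatrix:
    """Leave-one-out cross-validation; returns the confusion matrix.

    Every state is classified against all remaining states.  Requires at
    least two classes and two states per class (a singleton could never be
    matched with its own label).
    """
    labels = state_set.labels
    if len(set(labels)) < 2:
        raise ValueError("LOOCV needs at least 2 classes")
    for m in state_set.classes:
        if labels.count(m) < 2:
            raise ValueError(f"class {m!r} has a single state; LOOCV undefined")
    n = len(state_set)
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} training states per fold")
    D = pairwise_dissimilarity(state_set.matrix())
    idx = {m: i for i, m in enumerate(MOVEMENTS)}
    counts = np.zeros((len(MOVEMENTS), len(MOVEMENTS)), dtype=int)
    rest = np.arange(n)
    for i in range(n):
        others = rest[rest != i]
        pred = _predict(D[i, others], [labels[j] for j in others], k)
        counts[idx[labels[i]], idx[pred]] += 1
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall classification accuracy: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_true_positive_rate(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sums, in fixed class order (the per-limb polygon plot)."""
    row_sums = cm.counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [cm.classes[i] for i in np.nonzero(row_sums == 0)[0]]
        raise ValueError(f"classes with no trials: {empty}")
    return np.diag(cm.counts) / row_sums


def reliable_movement_count(cm: ConfusionMatrix, threshold: float = 0.80) -> int:
    """Number of movements whose true-positive rate reaches ``threshold``.

    Rows with no trials simply do not count as reliable.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    row_sums = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row_sums > 0, np.diag(cm.counts) / np.maximum(row_sums, 1), np.nan)
    return int(np.sum(tpr[~np.isnan(tpr)] >= threshold))


def end_state_set(ts: TrialSet, mask: FeatureMask, n_end: int = 5) -> LabeledStateSet:
    """End muscle states (mean of last ``n_end`` frames) for every trial."""
    return LabeledStateSet.from_states(end_muscle_state(t, mask, n_end) for t in ts)


def initial_state_set(ts: TrialSet, mask: FeatureMask) -> LabeledStateSet:
    """Initial muscle states (first frame) for every trial."""
    return LabeledStateSet.from_states(initial_muscle_state(t, mask) for t in ts)


def start_vs_end_accuracy(ts: TrialSet, mask: FeatureMask, k: int = 1,
                          n_end: int = 5) -> tuple[float, float]:
    """LOOCV accuracy on initial states vs end states, same mask and k.

    A clear end-over-initial gap indicates genuinely distinct volitional
    muscle activity rather than a biased starting posture.
    """
    init_acc = accuracy(loocv(initial_state_set(ts, mask), k))
    end_acc = accuracy(loocv(end_state_set(ts, mask, n_end), k))
    return init_acc, end_acc
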