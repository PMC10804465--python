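"""Representational similarity analysis of movement muscle states.

Two kinds of dissimilarity matrix are computed over condition-average end
states:

* the split-data RDM (sdRDM): trials of each movement are split in half and
  entry (i, j) is the Pearson dissimilarity between split-A's mean state of
  movement i and split-B's mean state of movement j.  The diagonal estimates
  within-movement (noise) dissimilarity and is generally nonzero; the matrix
  is generally not symmetric.
* the movement RDM: whole-set mean states, hence symmetric with a zero
  diagonal; used to compare representational structure across limbs.

The exemplar discriminability index (EDI) summarizes an sdRDM as the mean
off-diagonal minus the mean diagonal entry.  Significance is assessed with
exhaustive condition-label randomization: with six movements there are
exactly 6! = 720 label permutations, so the null distribution is enumerated
completely rather than sampled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import MOVEMENTS
from .classification import LabeledStateSet
from .preprocessing import MuscleState, pearson_dissimilarity


@dataclass
class SplitDataRDM:
    """Cross-split dissimilarity matrix; row = split-A label, col = split-B."""

    matrix: np.ndarray
    classes: tuple[str, ...] = MOVEMENTS
    split_policy: str = "contiguous"
    split_seed: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.classes)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n}")
        if self.matrix.min() < 0 or self.matrix.max() > 2:
            raise ValueError("Pearson dissimilarities must lie in [0, 2]")


@dataclass
class MovementRDM:
    """Symmetric zero-diagonal RDM over whole-set movement mean states."""

    matrix: np.ndarray
    classes: tuple[str, ...] = MOVEMENTS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.classes)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("movement RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("movement RDM must have a zero diagonal")


@dataclass
class PermutationTestResult:
    """Observed statistic, the complete enumerated null, and the p-value."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_permutations: int
    statistic_name: str

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_permutations:
            raise ValueError("null distribution length must equal n_permutations")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def split_trials(states: Sequence, policy: str = "contiguous", seed: int = 0):
    """Split one movement's trials into two halves.

    ``contiguous`` sends the first ⌈n/2⌉ trials (acquisition order) to half
    A and the rest to half B, so the sdRDM diagonal is sensitive to session
    drift; ``random`` applies a seeded shuffle first.
    """
    states = list(states)
    n = len(states)
    if n < 2:
        raise ValueError("need at least 2 trials per movement to split")
    idx = list(range(n))
    if policy == "random":
        rng = np.random.default_rng(seed)
        rng.shuffle(idx)
    elif policy != "contiguous":
        raise ValueError(f"unknown split policy {policy!r}")
    cut = math.ceil(n / 2)
    half_a = [states[i] for i in idx[:cut]]
    half_b = [states[i] for i in idx[cut:]]
    return half_a, half_b


def _mean_state(states: Sequence) -> np.ndarray:
    vecs = [s.values if isinstance(s, MuscleState) else np.asarray(s, float) for s in states]
    return np.mean(np.stack(vecs), axis=0)


def sdrdm(state_set: LabeledStateSet, policy: str = "contiguous", seed: int = 0) -> SplitDataRDM:
    """Split-data RDM: cross-split dissimilarity between movement means."""
    classes = tuple(state_set.classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 movements for an sdRDM")
    means_a, means_b = [], []
    for m in classes:
        half_a, half_b = split_trials(state_set.states_for(m), policy=policy, seed=seed)
        means_a.append(_mean_state(half_a))
        means_b.append(_mean_state(half_b))
    n = len(classes)
    matrix = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            matrix[i, j] = pearson_dissimilarity(means_a[i], means_b[j])
    return SplitDataRDM(matrix=matrix, classes=classes, split_policy=policy, split_seed=seed)


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, (SplitDataRDM, MovementRDM)):
        return m.matrix
    return np.asarray(m, dtype=float)


def edi(m) -> float:
    """Exemplar discriminability index of an sdRDM.

    Mean of the off-diagonal (between-movement) entries minus mean of the
    diagonal (within-movement) entries; positive when movements are more
    dissimilar to each other than each is to itself across splits.
    """
    matrix = _as_matrix(m)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or n < 2:
        raise ValueError("EDI needs a square matrix of size >= 2")
    diag = np.diag(matrix)
    off_mean = (matrix.sum() - diag.sum()) / (n * n - n)
    return float(off_mean - diag.mean())


def edi_permutation_test(m) -> PermutationTestResult:
    """Exhaustive label-randomization test of the EDI.

    One split's movement labels are permuted, which permutes the rows of the
    sdRDM; the EDI is recomputed for every permutation (720 for six
    movements, identity included).  p = #(null ≥ observed) / n_permutations,
    so p ≥ 1/720 always.
    """
    matrix = _as_matrix(m)
    n = matrix.shape[0]
    total = matrix.sum()
    off_n = n * n - n
    null = np.empty(math.factorial(n))
    cols = np.arange(n)
    for i, perm in enumerate(itertools.permutations(range(n))):
        diag_sum = matrix[np.asarray(perm), cols].sum()
        null[i] = (total - diag_sum) / off_n - diag_sum / n
    # the identity permutation is enumerated first; taking the observed value
    # from the null array keeps it bit-identical to its null entry, so the
    # count below always includes it and p >= 1/n!.
    observed = float(null[0])
    p = float(np.count_nonzero(null >= observed)) / len(null)
    return PermutationTestResult(
        observed=observed,
        null_values=null,
        p_value=p,
        n_permutations=len(null),
        statistic_name="edi",
    )


def movement_rdm(state_set: LabeledStateSet) -> MovementRDM:
    """Symmetric RDM over whole-set movement mean states (zero diagonal)."""
    classes = tuple(state_set.classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 movements for an RDM")
    means = [_mean_state(state_set.states_for(m)) for m in classes]
    n = len(classes)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pearson_dissimilarity(means[i], means[j])
            matrix[i, j] = matrix[j, i] = d
    return MovementRDM(matrix=matrix, classes=classes)


def _upper_triangle(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def rdm_correlation(a, b) -> float:
    """Pearson correlation of the two RDMs' upper-triangle entries.

    The structural zeros of the diagonal are excluded — including them would
    inflate the correlation.  For six movements this correlates two
    15-vectors in a fixed order.
    """
    ma, mb = _as_matrix(a), _as_matrix(b)
    if ma.shape != mb.shape:
        raise ValueError("RDMs must share one shape")
    ta, tb = _upper_triangle(ma), _upper_triangle(mb)
    if ta.std() == 0 or tb.std() == 0:
        raise ValueError("constant off-diagonal entries; correlation undefined")
    r = float(np.corrcoef(ta, tb)[0, 1])
    return max(-1.0, min(1.0, r))


def rdm_comparison_test(a, b) -> PermutationTestResult:
    """Exhaustive test of cross-limb RDM relatedness.

    For each of the 720 movement-label permutations, rows and columns of
    ``b`` are permuted simultaneously and the upper-triangle correlation
    with the unpermuted ``a`` recomputed; p = #(null ≥ observed) / 720.
    """
    ma, mb = _as_matrix(a), _as_matrix(b)
    n = ma.shape[0]
    ta = _upper_triangle(ma)
    if ta.std() == 0:
        raise ValueError("constant off-diagonal entries in a; correlation undefined")
    null = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(range(n))):
        p = np.asarray(perm)
        tb = _upper_triangle(mb[np.ix_(p, p)])
        if tb.std() == 0:
            raise ValueError("constant off-diagonal entries in b; correlation undefined")
        null[i] = np.corrcoef(ta, tb)[0, 1]
    observed = float(null[0])  # identity permutation enumerated first
    p_value = float(np.count_nonzero(null >= observed)) / len(null)
    return PermutationTestResult(
        observed=observed,
        null_values=null,
        p_value=p_value,
        n_permutations=len(null),
        statistic_name="rdm_correlation",
    )


def compare_limb_edi(affected: PermutationTestResult, unaffected: PermutationTestResult,
                     alpha: float = 0.05, subject_id: str = "") -> pd.DataFrame:
    """Tabulate EDI and randomization p-value per limb, flagged at ``alpha``.

    One row per limb; concatenating over subjects reproduces the per-subject
    per-limb summary table layout.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for limb, result in (("affected", affected), ("unaffected", unaffected)):
        rows.append(
            {
                "subject_id": subject_id,
                "limb": limb,
                "edi": result.observed,
                "p_value": result.p_value,
                "n_permutations": result.n_permutations,
                "significant": result.p_value <= alpha,
            }
        )
    return pd.DataFrame(rows)
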