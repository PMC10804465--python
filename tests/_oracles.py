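"""Independent brute-force reference implementations used as test oracles.

Everything here is written the slow, obvious way (explicit loops, scipy's
pearsonr) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
from scipy.stats import pearsonr

from sonorsa.io_core import MOVEMENTS


def oracle_dissimilarity(a, b) -> float:
    return 1.0 - pearsonr(np.asarray(a, float), np.asarray(b, float)).statistic


def oracle_downsample(frame: np.ndarray, target) -> np.ndarray:
    tr, tc = target
    r, c = frame.shape
    br, bc = r // tr, c // tc
    out = np.empty((tr, tc))
    for i in range(tr):
        for j in range(tc):
            out[i, j] = frame[i * br:(i + 1) * br, j * bc:(j + 1) * bc].mean()
    return out


def oracle_predict(dists, labels, k: int) -> str:
    """Explicitly sorted KNN with the same deterministic tie rules."""
    ranked = sorted(range(len(labels)), key=lambda i: (dists[i], i))[:k]
    votes = Counter(labels[i] for i in ranked)
    top = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == top)
    nearest = {c: min(dists[i] for i in ranked if labels[i] == c) for c in tied}
    return min(tied, key=lambda c: (nearest[c], MOVEMENTS.index(c)))


def oracle_loocv(vectors: np.ndarray, labels, k: int = 1) -> np.ndarray:
    """Confusion matrix in the fixed class order via explicit pair loops."""
    n = len(labels)
    idx = {m: i for i, m in enumerate(MOVEMENTS)}
    counts = np.zeros((6, 6), dtype=int)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        d = [oracle_dissimilarity(vectors[i], vectors[j]) for j in others]
        pred = oracle_predict(d, [labels[j] for j in others], k)
        counts[idx[labels[i]], idx[pred]] += 1
    return counts


def oracle_sdrdm(vectors: np.ndarray, labels, classes) -> np.ndarray:
    """Contiguous split halves, per-movement means, cross-split distances."""
    n = len(classes)
    means_a, means_b = [], []
    for m in classes:
        vs = [vectors[i] for i in range(len(labels)) if labels[i] == m]
        cut = (len(vs) + 1) // 2
        means_a.append(np.mean(vs[:cut], axis=0))
        means_b.append(np.mean(vs[cut:], axis=0))
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = oracle_dissimilarity(means_a[i], means_b[j])
    return out


def oracle_edi(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    diag = [matrix[i, i] for i in range(n)]
    off = [matrix[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(off) - np.mean(diag))


def oracle_edi_permutation(matrix: np.ndarray):
    """Row-permuted EDI null by explicitly permuting the matrix."""
    n = matrix.shape[0]
    null = []
    for perm in itertools.permutations(range(n)):
        permuted = matrix[list(perm), :]
        null.append(oracle_edi(permuted))
    observed = null[0]
    p = sum(v >= observed for v in null) / len(null)
    return observed, np.array(null), p


def oracle_rdm_comparison(a: np.ndarray, b: np.ndarray):
    """Simultaneous row/col permutation null for the RDM correlation."""
    n = a.shape[0]
    tri = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ta = [a[i, j] for i, j in tri]
    null = []
    for perm in itertools.permutations(range(n)):
        tb = [b[perm[i], perm[j]] for i, j in tri]
        null.append(pearsonr(ta, tb).statistic)
    observed = null[0]
    p = sum(v >= observed for v in null) / len(null)
    return observed, np.array(null), p
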