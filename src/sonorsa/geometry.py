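"""Full-trial muscle-state trajectories: frame distances and classical MDS.

Every frame of every trial of one limb is treated as a point; the pairwise
Pearson dissimilarity matrix over all frames is embedded with classical
(Torgerson) multidimensional scaling.  The embedding visualizes how each
movement travels from the shared rest state to its held end state; the
trajectory-separation index quantifies whether movement end regions stay
spatially distinct (evidence against a single shared compensatory path).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io_core import MOVEMENTS, TrialSet
from .preprocessing import DegenerateStateError, FeatureMask, extract_features, pairwise_dissimilarity

#: above this matrix size the full spectrum is skipped in favour of the
#: top-d Lanczos eigenpairs (the only ones the embedding needs)
_FULL_EIG_MAX_N = 1200


@dataclass
class FrameDistanceMatrix:
    """All-frames Pearson dissimilarity matrix with a frame → (trial, time) map."""

    matrix: np.ndarray
    frame_info: pd.DataFrame  # columns: trial_key, movement, trial_index, frame, n_frames

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.frame_info) != n:
            raise ValueError("matrix and frame map sizes disagree")


@dataclass
class MDSEmbedding:
    """Classical MDS coordinates plus diagnostics.

    ``stress`` is the normalized root-mean-square error between the input
    dissimilarities and the embedded Euclidean distances.  Pearson
    dissimilarities are not guaranteed Euclidean; negative eigenvalues are
    truncated to zero and their total magnitude reported as
    ``negative_eigenvalue_mass`` (NaN when the full spectrum was not
    computed).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    stress: float
    frame_info: pd.DataFrame
    negative_eigenvalue_mass: float = float("nan")

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n, d = self.coordinates.shape
        if d > max(n - 1, 0):
            raise ValueError("embedding dimension must be <= n - 1")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")


def frame_distance_matrix(ts: TrialSet, mask: FeatureMask) -> FrameDistanceMatrix:
    """Pairwise Pearson dissimilarity between every frame of every trial."""
    vectors, records = [], []
    for t in ts:
        feats = t.frames[:, mask.keep]
        sd = feats.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.nonzero(sd == 0)[0][0])
            raise DegenerateStateError(
                f"zero-variance frame: trial {t.key}, frame {bad}"
            )
        vectors.append(feats)
        for f in range(t.n_frames):
            records.append(
                {
                    "trial_key": "/".join(map(str, t.key)),
                    "movement": t.movement,
                    "trial_index": t.trial_index,
                    "frame": f,
                    "n_frames": t.n_frames,
                }
            )
    X = np.concatenate(vectors, axis=0)
    D = pairwise_dissimilarity(X)
    return FrameDistanceMatrix(matrix=D, frame_info=pd.DataFrame(records))


def classical_mds(dm, d: int = 3) -> MDSEmbedding:
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Double-centres the squared dissimilarities, eigendecomposes the Gram
    matrix, and scales the top-``d`` eigenvectors by the square roots of
    their eigenvalues.  Deterministic — no random initialization.  If fewer
    than ``d`` eigenvalues are positive the surplus dimensions are zero
    (with a warning).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if isinstance(dm, FrameDistanceMatrix):
        D, frame_info = dm.matrix, dm.frame_info
    else:
        D = np.asarray(dm, dtype=float)
        frame_info = pd.DataFrame({"frame": np.arange(D.shape[0])})
    n = D.shape[0]
    if d > n - 1:
        raise ValueError(f"d={d} must be <= n-1={n - 1}")
    D2 = D ** 2
    # B = -1/2 J D^2 J without materializing J
    row_mean = D2.mean(axis=1, keepdims=True)
    B = -0.5 * (D2 - row_mean - row_mean.T + D2.mean())
    B = 0.5 * (B + B.T)

    neg_mass = float("nan")
    if n <= _FULL_EIG_MAX_N:
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        neg_mass = float(-evals[evals < 0].sum())
        evals_d, evecs_d = evals[:d], evecs[:, :d]
    else:
        from scipy.sparse.linalg import eigsh

        evals_d, evecs_d = eigsh(B, k=d, which="LA")
        order = np.argsort(evals_d)[::-1]
        evals_d, evecs_d = evals_d[order], evecs_d[:, order]

    tol = np.max(np.abs(evals_d)) * 1e-9 if evals_d.size else 0.0
    n_pos = int(np.count_nonzero(evals_d > tol))
    if n_pos < d:
        warnings.warn(
            f"only {n_pos} positive eigenvalues for a {d}-D embedding; "
            "surplus dimensions are zero",
            stacklevel=2,
        )
    coords = evecs_d * np.sqrt(np.where(evals_d > tol, evals_d, 0.0))
    embedded = squareform(pdist(coords))
    denom = float(np.sum(D ** 2))
    stress = 0.0 if denom == 0 else float(np.sqrt(np.sum((D - embedded) ** 2) / denom))
    return MDSEmbedding(
        coordinates=coords,
        eigenvalues=evals_d,
        stress=stress,
        frame_info=frame_info,
        negative_eigenvalue_mass=neg_mass,
    )


def trajectory_separation(emb: MDSEmbedding, hold_fraction: float = 0.25) -> dict:
    """Per-movement-pair separation of the embedded hold-phase frames.

    For each trial the final ``hold_fraction`` of its frames (the held end
    state) is kept.  For a movement pair, the index is

        (between-centroid distance − mean within-movement spread)
        / max(between, within)

    with 0/0 defined as 0.  Positive values mean the two movements' end
    regions are spatially separate in the embedding.
    """
    if not 0 < hold_fraction <= 1:
        raise ValueError("hold_fraction must lie in (0, 1]")
    info = emb.frame_info
    required = {"movement", "n_frames", "frame"}
    if not required <= set(info.columns):
        raise ValueError("embedding lacks the trial/frame map needed for trajectories")
    n_hold = np.maximum(1, np.ceil(hold_fraction * info["n_frames"]).astype(int))
    hold = info["frame"] >= info["n_frames"] - n_hold
    pts = {
        m: emb.coordinates[((info["movement"] == m) & hold).to_numpy()]
        for m in info["movement"].unique()
    }
    movements = [m for m in MOVEMENTS if m in pts]
    centroids = {m: p.mean(axis=0) for m, p in pts.items()}
    spreads = {
        m: float(np.linalg.norm(p - centroids[m], axis=1).mean()) for m, p in pts.items()
    }
    result = {}
    for m1, m2 in itertools.combinations(movements, 2):
        between = float(np.linalg.norm(centroids[m1] - centroids[m2]))
        within = 0.5 * (spreads[m1] + spreads[m2])
        denom = max(between, within)
        result[(m1, m2)] = 0.0 if denom == 0 else (between - within) / denom
    return result
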