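"""Raw frame sequences → masked muscle-state feature vectors.

The preprocessing chain mirrors standard sonomyography practice: block-mean
downsampling of each frame, removal of pixels that never deviate from their
initial value in any trial (screen regions outside the ultrasound image),
and summary "muscle states" — the first frame of a trial (initial state,
rest) and the mean of the last five frames (end state, held movement).  All
distances downstream are the Pearson dissimilarity 1 − r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import TrialRecording, TrialSet


class DegenerateStateError(ValueError):
    """A feature vector has zero variance; Pearson correlation is undefined."""


@dataclass
class FeatureMask:
    """Boolean grid of pixels retained for analysis (True = kept)."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValueError("mask must be a 2-D boolean grid")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.keep.shape  # type: ignore[return-value]

    def to_csv(self, path: str | Path) -> Path:
        """Persist as (row, col) coordinates of kept pixels, row-major, 0-based."""
        rows, cols = np.nonzero(self.keep)
        pd.DataFrame({"row": rows, "col": cols}).to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path, shape: tuple[int, int]) -> "FeatureMask":
        df = pd.read_csv(path)
        keep = np.zeros(shape, dtype=bool)
        keep[df["row"].to_numpy(), df["col"].to_numpy()] = True
        return cls(keep=keep)


@dataclass
class MuscleState:
    """Feature vector for one frame (or frame-average) after masking."""

    values: np.ndarray
    source: str = "frame"  # one of: initial, end, frame
    subject_id: str = ""
    limb: str = ""
    movement: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("muscle state contains non-finite values")
        if self.source not in ("initial", "end", "frame"):
            raise ValueError(f"unknown source {self.source!r}")


def downsample_frame(frame: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Block-mean downsampling; each output pixel averages its source block.

    Requires the frame dimensions to be integer multiples of the target.
    Block-mean is deterministic, interpolation-free and preserves the global
    mean intensity.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    tr, tc = int(target[0]), int(target[1])
    r, c = frame.shape
    if r % tr or c % tc:
        raise ValueError(f"frame shape {frame.shape} is not divisible by target {(tr, tc)}")
    return frame.reshape(tr, r // tr, tc, c // tc).mean(axis=(1, 3))


def downsample_trial(trial: TrialRecording, target: tuple[int, int]) -> TrialRecording:
    """Downsample every frame of a trial (vectorized block mean)."""
    tr, tc = int(target[0]), int(target[1])
    n, r, c = trial.frames.shape
    if r % tr or c % tc:
        raise ValueError(f"frame shape {(r, c)} is not divisible by target {(tr, tc)}")
    frames = trial.frames.reshape(n, tr, r // tr, tc, c // tc).mean(axis=(2, 4))
    return TrialRecording(
        subject_id=trial.subject_id,
        limb=trial.limb,
        movement=trial.movement,
        trial_index=trial.trial_index,
        frames=frames,
        frame_rate_hz=trial.frame_rate_hz,
    )


def downsample_trial_set(ts: TrialSet, target: tuple[int, int]) -> TrialSet:
    return TrialSet(
        trials=[downsample_trial(t, target) for t in ts.trials],
        metadata=dict(ts.metadata),
    )


def build_static_pixel_mask(trials: Sequence[TrialRecording], tol: float = 0.0) -> FeatureMask:
    """Keep a pixel iff it deviates from its trial-initial value in any trial.

    A pixel is retained when, in at least one trial, some frame differs from
    that trial's first frame by more than ``tol`` at that pixel.  With the
    default ``tol = 0`` this removes exactly the pixels that never change —
    in real captures, screen furniture outside the ultrasound image.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial to build a mask")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    shape = trials[0].frame_shape
    for t in trials:
        if t.frame_shape != shape:
            raise ValueError("all trials must share one downsampled frame shape")
    keep = np.zeros(shape, dtype=bool)
    for t in trials:
        dev = np.abs(t.frames - t.frames[0]) > tol
        keep |= dev.any(axis=0)
    mask = FeatureMask(keep=keep)
    if mask.n_kept < 2:
        raise DegenerateStateError(
            f"only {mask.n_kept} pixel(s) deviate (tol={tol}); Pearson dissimilarity needs >= 2"
        )
    return mask


def extract_features(frame: np.ndarray, mask: FeatureMask, **labels) -> MuscleState:
    """Flatten a frame's kept pixels in fixed row-major order."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.shape:
        raise ValueError(f"frame shape {frame.shape} does not match mask shape {mask.shape}")
    return MuscleState(values=frame[mask.keep], **labels)


def initial_muscle_state(trial: TrialRecording, mask: FeatureMask) -> MuscleState:
    """The first frame of a trial — the resting muscle configuration."""
    return extract_features(
        trial.frames[0],
        mask,
        source="initial",
        subject_id=trial.subject_id,
        limb=trial.limb,
        movement=trial.movement,
        trial_index=trial.trial_index,
    )


def end_muscle_state(trial: TrialRecording, mask: FeatureMask, n_end: int = 5) -> MuscleState:
    """Mean of the last ``n_end`` frames — the held end-of-movement state."""
    if n_end < 1:
        raise ValueError("n_end must be a positive integer")
    if trial.n_frames < n_end:
        raise ValueError(
            f"trial has {trial.n_frames} frames, fewer than n_end={n_end}"
        )
    mean_frame = trial.frames[-n_end:].mean(axis=0)
    return extract_features(
        mean_frame,
        mask,
        source="end",
        subject_id=trial.subject_id,
        limb=trial.limb,
        movement=trial.movement,
        trial_index=trial.trial_index,
    )


def _as_vector(x) -> np.ndarray:
    if isinstance(x, MuscleState):
        return x.values
    return np.asarray(x, dtype=float).ravel()


def pearson_dissimilarity(a, b) -> float:
    """d = 1 − r, the Pearson correlation distance, in [0, 2].

    Perfectly correlated states are at distance 0, anticorrelated states at
    2.  Raises :class:`DegenerateStateError` when either vector has zero
    variance (the correlation is undefined there and signals a degenerate
    muscle state upstream).
    """
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape[0]} vs {vb.shape[0]}")
    if va.size < 2:
        raise ValueError("Pearson dissimilarity needs vectors of length >= 2")
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise DegenerateStateError("zero-variance input; Pearson correlation undefined")
    r = float(np.dot(va - va.mean(), vb - vb.mean()) / (va.size * sa * sb))
    return 1.0 - min(1.0, max(-1.0, r))


def pairwise_dissimilarity(vectors: np.ndarray) -> np.ndarray:
    """All-pairs Pearson dissimilarity for the rows of ``vectors``.

    Equivalent to looping :func:`pearson_dissimilarity` but vectorized;
    raises on any zero-variance row.
    """
    X = np.asarray(vectors, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise DegenerateStateError(f"zero-variance feature vector at row {bad}")
    D = 1.0 - np.clip(np.corrcoef(X), -1.0, 1.0)
    D = 0.5 * (D + D.T)  # exact symmetry despite float rounding
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)
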