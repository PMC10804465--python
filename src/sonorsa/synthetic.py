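"""Synthetic paired-limb sonomyography trial sets with known ground truth.

Real recordings of this kind are forearm ultrasound sequences: each trial
starts at rest, ramps into a movement-specific tissue-deformation pattern,
and holds it until the trial ends.  The generator emulates exactly that
contract:

* a smooth resting intensity field shared by all trials of a limb,
* one deformation prototype per movement (rest plus a sum of Gaussian
  bumps), pairwise distinct for distinct seeds,
* a monotone logistic activation ramp, normalized so the first frame equals
  rest exactly and the final 0.5 s holds the full prototype exactly,
* per-trial amplitude jitter, i.i.d. pixel noise, and a static border of
  pixels that never change (emulating screen regions without image data),
* a shared-weight parameter w mixing the two limbs' prototype deviations,
  so the expected cross-limb representational similarity is controllable
  (w = 1: identical structure; w = 0: independent).

Every output is a pure function of (configuration, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_core import MOVEMENTS, TrialRecording, TrialSet


@dataclass
class SyntheticGroundTruth:
    """Generative parameters against which pipeline recovery is tested."""

    rest_pattern: np.ndarray
    prototypes_unaffected: list
    prototypes_affected: list
    shared_weight: float = 0.9
    noise_sd: float = 100.0
    amplitude_jitter_sd: float = 0.1
    ramp_midpoint_s: float = 2.0
    ramp_steepness: float = 5.0
    n_trials_per_movement: int = 5
    frame_rate_hz: float = 30.0
    trial_seconds: float = 4.0
    static_margin: int = 4
    raw_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if not 0 <= self.shared_weight <= 1:
            raise ValueError("shared_weight must lie in [0, 1]")
        if self.noise_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 5 <= self.n_trials_per_movement <= 10:
            raise ValueError("n_trials_per_movement must lie in [5, 10]")
        if self.static_margin < 0:
            raise ValueError("static_margin must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_seconds * self.frame_rate_hz))

    def to_json(self, path: str | Path) -> Path:
        """Persist the scalar parameters (fields, not the pixel arrays)."""
        d = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("rest_pattern", "prototypes_unaffected", "prototypes_affected")
        }
        d["raw_size"] = list(self.raw_size)
        Path(path).write_text(json.dumps(d, indent=2))
        return Path(path)


def _margin_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    """Boolean grid, True on the interior (outside the static border)."""
    interior = np.zeros(shape, dtype=bool)
    if margin == 0:
        interior[:] = True
    elif 2 * margin < min(shape):
        interior[margin:-margin, margin:-margin] = True
    return interior


def _gaussian_bump(shape, center, sigma, amplitude) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma ** 2)
    )


def make_rest_pattern(raw_size: tuple[int, int] = (256, 256), seed: int = 0) -> np.ndarray:
    """Smooth nonnegative resting intensity field (broad seeded bumps)."""
    rng = np.random.default_rng(seed)
    shape = tuple(raw_size)
    rest = np.full(shape, 100.0)
    sigma = min(shape) / 4
    for _ in range(6):
        center = rng.uniform([0, 0], shape)
        amp = rng.uniform(-30, 30)
        rest += _gaussian_bump(shape, center, sigma, amp)
    return np.clip(rest, 10.0, None)


def make_prototypes(
    n_movements: int,
    raw_size: tuple[int, int] = (256, 256),
    n_blobs: int = 6,
    seed: int = 0,
    rest: np.ndarray | None = None,
    amplitude: float = 40.0,
    width_frac: float = 1 / 12,
    static_margin: int = 0,
) -> list:
    """One end-state deformation prototype per movement.

    Each prototype is the rest pattern plus ``n_blobs`` isotropic Gaussian
    bumps with seeded per-movement positions and signed amplitudes; the
    deviation is zeroed on the static border so border pixels stay constant
    through entire trials.  Deterministic given the seed.
    """
    if n_movements < 2:
        raise ValueError("need at least 2 movements")
    rng = np.random.default_rng(seed)
    shape = tuple(raw_size)
    if rest is None:
        rest = np.zeros(shape)
    interior = _margin_mask(shape, static_margin)
    sigma = width_frac * min(shape)
    margin = static_margin
    protos = []
    for _ in range(n_movements):
        dev = np.zeros(shape)
        for _ in range(n_blobs):
            center = rng.uniform(
                [margin + sigma, margin + sigma],
                [shape[0] - margin - sigma, shape[1] - margin - sigma],
            )
            amp = amplitude * rng.uniform(0.6, 1.4) * rng.choice([-1.0, 1.0])
            dev += _gaussian_bump(shape, center, sigma, amp)
        dev[~interior] = 0.0
        protos.append(rest + dev)
    return protos


def make_affected_prototypes(
    unaffected: list,
    w: float,
    seed: int = 0,
    rest: np.ndarray | None = None,
    n_blobs: int = 6,
    amplitude: float = 40.0,
    static_margin: int = 0,
) -> list:
    """Affected-limb prototypes sharing a fraction ``w`` of structure.

    affected_m = rest + w·(unaffected_m − rest) + (1 − w)·independent_m
    where independent_m is a fresh prototype deviation from the seeded
    generator.  w = 1 reproduces the unaffected deviations exactly; w = 0
    gives fully independent structure.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    shape = np.asarray(unaffected[0]).shape
    if rest is None:
        rest = np.zeros(shape)
    indep = make_prototypes(
        len(unaffected),
        raw_size=shape,
        n_blobs=n_blobs,
        seed=seed,
        rest=None,
        amplitude=amplitude,
        static_margin=static_margin,
    )
    return [rest + w * (u - rest) + (1 - w) * dev for u, dev in zip(unaffected, indep)]


def default_ground_truth(
    seed: int = 0,
    raw_size: tuple[int, int] = (256, 256),
    shared_weight: float = 0.9,
    noise_sd: float = 100.0,
    amplitude_jitter_sd: float = 0.1,
    n_trials_per_movement: int = 5,
    static_margin: int = 4,
    n_blobs: int = 6,
    blob_amplitude: float = 40.0,
) -> SyntheticGroundTruth:
    """Build a complete paired-limb ground truth from one seed.

    Prototype, rest-field and cross-limb seeds are drawn from one seeded
    stream so the whole object is a pure function of ``seed``.
    """
    rng = np.random.default_rng(seed)
    s_rest, s_unaff, s_aff = rng.integers(0, 2**31 - 1, size=3)
    rest = make_rest_pattern(raw_size, seed=int(s_rest))
    unaff = make_prototypes(
        len(MOVEMENTS),
        raw_size=raw_size,
        n_blobs=n_blobs,
        seed=int(s_unaff),
        rest=rest,
        amplitude=blob_amplitude,
        static_margin=static_margin,
    )
    aff = make_affected_prototypes(
        unaff,
        w=shared_weight,
        seed=int(s_aff),
        rest=rest,
        n_blobs=n_blobs,
        amplitude=blob_amplitude,
        static_margin=static_margin,
    )
    return SyntheticGroundTruth(
        rest_pattern=rest,
        prototypes_unaffected=unaff,
        prototypes_affected=aff,
        shared_weight=shared_weight,
        noise_sd=noise_sd,
        amplitude_jitter_sd=amplitude_jitter_sd,
        n_trials_per_movement=n_trials_per_movement,
        static_margin=static_margin,
        raw_size=tuple(raw_size),
    )


def activation_ramp(gt: SyntheticGroundTruth) -> np.ndarray:
    """Per-frame activation s(t) in [0, 1]: 0 at t = 0, 1 for the last 0.5 s.

    A logistic curve normalized between its value at t = 0 and at the start
    of the hold window, then clamped — monotone, rest-start, hold-end.
    """
    t = np.arange(gt.n_frames) / gt.frame_rate_hz
    t_hold = gt.trial_seconds - 0.5
    u = 1.0 / (1.0 + np.exp(-gt.ramp_steepness * (t - gt.ramp_midpoint_s)))
    u0 = 1.0 / (1.0 + math.exp(gt.ramp_steepness * gt.ramp_midpoint_s))
    uh = 1.0 / (1.0 + math.exp(-gt.ramp_steepness * (t_hold - gt.ramp_midpoint_s)))
    return np.clip((u - u0) / (uh - u0), 0.0, 1.0)


def generate_trial(
    proto: np.ndarray,
    gt: SyntheticGroundTruth,
    seed: int,
    subject_id: str = "synthetic",
    limb: str = "affected",
    movement: str = "power",
    trial_index: int = 1,
) -> TrialRecording:
    """One trial: rest → logistic ramp into the prototype → hold, plus noise.

    frame(t) = rest + s(t)·a·(proto − rest) + ε(t) with a ~ N(1, jitter²)
    per trial and ε i.i.d. N(0, σ²) per pixel per frame; the static border
    carries neither deviation nor noise.
    """
    rng = np.random.default_rng(seed)
    rest = gt.rest_pattern
    s = activation_ramp(gt).astype(np.float32)
    a = 1.0 + gt.amplitude_jitter_sd * rng.standard_normal()
    dev = (np.asarray(proto) - rest).astype(np.float32) * np.float32(a)
    frames = rest.astype(np.float32)[None] + s[:, None, None] * dev[None]
    if gt.noise_sd > 0:
        noise = rng.standard_normal(frames.shape, dtype=np.float32) * np.float32(gt.noise_sd)
        interior = _margin_mask(rest.shape, gt.static_margin)
        noise[:, ~interior] = 0.0
        frames = frames + noise
    return TrialRecording(
        subject_id=subject_id,
        limb=limb,
        movement=movement,
        trial_index=trial_index,
        frames=frames,
        frame_rate_hz=gt.frame_rate_hz,
        trial_window_s=gt.trial_seconds,
    )


def _trial_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def generate_subject(gt: SyntheticGroundTruth, seed: int):
    """Full paired-limb trial sets for one synthetic subject.

    Returns ``(affected TrialSet, unaffected TrialSet, gt)``; the ground
    truth is passed through for recovery tests.  Bit-identical for equal
    seeds.
    """
    ntr = gt.n_trials_per_movement
    seeds = _trial_seeds(seed, 2 * len(MOVEMENTS) * ntr)
    subject_id = f"synthetic-{seed}"
    sets = {}
    i = 0
    for limb, protos in (
        ("affected", gt.prototypes_affected),
        ("unaffected", gt.prototypes_unaffected),
    ):
        trials = []
        for movement, proto in zip(MOVEMENTS, protos):
            for trial in range(1, ntr + 1):
                trials.append(
                    generate_trial(
                        proto, gt, int(seeds[i]),
                        subject_id=subject_id, limb=limb,
                        movement=movement, trial_index=trial,
                    )
                )
                i += 1
        sets[limb] = TrialSet(trials=trials, metadata={"seed": seed, "limb": limb})
    return sets["affected"], sets["unaffected"], gt


def generate_null_subject(gt: SyntheticGroundTruth, seed: int) -> TrialSet:
    """A subject in which all movements share one prototype.

    Only noise differs between movements, so the movement labels are
    exchangeable by construction — the null hypothesis of the EDI
    label-randomization test holds exactly.
    """
    ntr = gt.n_trials_per_movement
    seeds = _trial_seeds(seed, len(MOVEMENTS) * ntr)
    proto = gt.prototypes_unaffected[0]
    trials = []
    i = 0
    for movement in MOVEMENTS:
        for trial in range(1, ntr + 1):
            trials.append(
                generate_trial(
                    proto, gt, int(seeds[i]),
                    subject_id=f"null-{seed}", limb="affected",
                    movement=movement, trial_index=trial,
                )
            )
            i += 1
    return TrialSet(trials=trials, metadata={"seed": seed, "null": True})
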