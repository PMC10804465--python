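"""Convenience entry points running the full per-limb analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import classification, geometry, preprocessing, rsa
from .io_core import RunConfig, TrialSet
from .preprocessing import FeatureMask


@dataclass
class LimbAnalysis:
    """Everything the pipeline computes for one limb of one subject."""

    mask: FeatureMask
    end_states: classification.LabeledStateSet
    confusion: classification.ConfusionMatrix
    accuracy: float
    tpr: np.ndarray
    reliable_movements: int
    sdrdm: rsa.SplitDataRDM
    edi_test: rsa.PermutationTestResult
    movement_rdm: rsa.MovementRDM


def preprocess_limb(ts: TrialSet, config: RunConfig | None = None):
    """Downsample a limb's trials and build its static-pixel mask.

    The mask is built per limb from that limb's trials only, so
    classification and RSA share one feature space per recording block.
    """
    config = config or RunConfig()
    down = preprocessing.downsample_trial_set(ts, config.downsample_to)
    mask = preprocessing.build_static_pixel_mask(down.trials, config.static_pixel_tolerance)
    return down, mask


def analyze_limb(ts: TrialSet, config: RunConfig | None = None) -> LimbAnalysis:
    """Run classification and RSA for one limb's raw trial set."""
    config = config or RunConfig()
    down, mask = preprocess_limb(ts, config)
    end = classification.end_state_set(down, mask, config.end_state_frames)
    cm = classification.loocv(end, config.k_neighbors)
    sd = rsa.sdrdm(end, policy=config.split_policy, seed=config.split_seed)
    return LimbAnalysis(
        mask=mask,
        end_states=end,
        confusion=cm,
        accuracy=classification.accuracy(cm),
        tpr=classification.per_class_true_positive_rate(cm),
        reliable_movements=classification.reliable_movement_count(cm, config.ca_threshold),
        sdrdm=sd,
        edi_test=rsa.edi_permutation_test(sd),
        movement_rdm=rsa.movement_rdm(end),
    )


def limb_trajectories(ts: TrialSet, config: RunConfig | None = None):
    """Frame-distance matrix, MDS embedding, and pair separation indices."""
    config = config or RunConfig()
    down, mask = preprocess_limb(ts, config)
    dm = geometry.frame_distance_matrix(down, mask)
    emb = geometry.classical_mds(dm, d=config.mds_dims)
    return dm, emb, geometry.trajectory_separation(emb)
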