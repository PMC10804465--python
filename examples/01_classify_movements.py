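"""Classify six attempted hand/wrist movements from synthetic ultrasound trials.

Generates one paired-limb synthetic subject (raw 64x64 frames, five trials
per movement), runs the standard pipeline — block-mean downsampling to
32x32, static-pixel masking, end-state extraction, 1-NN classification
under the Pearson dissimilarity with leave-one-out cross-validation — and
prints per-limb accuracy against the 16.7% chance level, the per-movement
true-positive rates, and how many movements clear the 80% reliability
threshold used to judge prosthesis-grade performance.
"""

import numpy as np

import sonorsa as s

gt = s.default_ground_truth(seed=0, raw_size=(64, 64))
affected, unaffected, _ = s.generate_subject(gt, seed=0)
config = s.RunConfig(downsample_to=(32, 32))

print(f"chance level: {100 * s.chance_level(6):.1f}%")
for limb, trial_set in (("affected", affected), ("unaffected", unaffected)):
    result = s.analyze_limb(trial_set, config)
    print(f"\n{limb} limb ({len(trial_set)} trials, "
          f"{result.mask.n_kept} pixels kept):")
    print(f"  LOOCV accuracy: {100 * result.accuracy:.1f}%")
    print(f"  movements at >=80% true-positive rate: "
          f"{result.reliable_movements} of 6")
    for movement, tpr in zip(s.MOVEMENTS, result.tpr):
        print(f"    {movement:<15s} {100 * tpr:5.1f}%")

print("\nAccuracy far above chance on both limbs means the generator's six "
      "deformation prototypes are recovered from noisy trials; a movement "
      "below 80% would be considered unreliable for prosthesis control.")
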