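"""How similarly do the two limbs represent the same movement set?

The shared-weight parameter w of the generator mixes the affected limb's
deformation prototypes from the unaffected limb's (w = 1: same structure,
w = 0: independent).  For each w we build a symmetric movement RDM per limb
from whole-set mean end states, correlate the 15 upper-triangle entries,
and test the correlation against the exhaustive 720-permutation null.
"""

import numpy as np

import sonorsa as s
from sonorsa import classification as cl, preprocessing as pp, rsa

TARGET = (16, 16)


def movement_rdm_for(ts):
    down = pp.downsample_trial_set(ts, TARGET)
    mask = pp.build_static_pixel_mask(down.trials)
    return rsa.movement_rdm(cl.end_state_set(down, mask))


print(f"{'w':>5s} {'mean r':>8s} {'p (seed 0)':>11s}   (5 seeds each)")
for w in (0.0, 0.5, 0.9, 1.0):
    corrs, p0 = [], None
    for seed in range(5):
        gt = s.default_ground_truth(seed=seed + 10, raw_size=(32, 32),
                                    shared_weight=w, noise_sd=20.0)
        aff, unaff, _ = s.generate_subject(gt, seed=seed + 20)
        ra, ru = movement_rdm_for(aff), movement_rdm_for(unaff)
        corrs.append(rsa.rdm_correlation(ra, ru))
        if seed == 0:
            p0 = rsa.rdm_comparison_test(ra, ru).p_value
    print(f"{w:5.1f} {np.mean(corrs):8.3f} {p0:11.4f}")

print("\nThe cross-limb RDM correlation tracks the planted shared weight: "
      "near zero for independent prototypes, near one when both limbs share "
      "their deformation structure, with the randomization test significant "
      "whenever real shared structure exists.")
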