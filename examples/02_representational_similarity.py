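"""Split-data RDM and exemplar discriminability index for one limb.

Trials of each movement are split in half; entry (i, j) of the split-data
RDM is the Pearson dissimilarity between split-A's mean muscle state of
movement i and split-B's of movement j.  The diagonal measures within-
movement (noise) dissimilarity, the off-diagonals between-movement
dissimilarity; their difference is the exemplar discriminability index
(EDI), tested with the exhaustive 720-permutation label randomization.
"""

import numpy as np
import pandas as pd

import sonorsa as s

gt = s.default_ground_truth(seed=1, raw_size=(64, 64))
affected, unaffected, _ = s.generate_subject(gt, seed=1)
config = s.RunConfig(downsample_to=(32, 32))

results = {}
for limb, trial_set in (("affected", affected), ("unaffected", unaffected)):
    analysis = s.analyze_limb(trial_set, config)
    results[limb] = analysis.edi_test
    if limb == "affected":
        print("affected-limb split-data RDM (rows: split A, cols: split B):")
        print(pd.DataFrame(np.round(analysis.sdrdm.matrix, 2),
                           index=s.MOVEMENTS, columns=s.MOVEMENTS))

table = s.compare_limb_edi(results["affected"], results["unaffected"],
                           alpha=0.05, subject_id="synthetic-1")
print("\n" + table.to_string(index=False))
print("\nA positive EDI with p = 1/720 (the smallest attainable p-value) "
      "means between-movement dissimilarities exceed within-movement ones "
      "under every relabeling: the movements are distinctly represented.")
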