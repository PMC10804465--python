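# Methods

## The analysis model

A recording session yields, per limb, 5–10 trials for each of six attempted
hand/wrist movements (power, point, pinch, key, wrist flexion, wrist
rotation). A trial is an ordered sequence of grayscale ultrasound frames
(nominally 30 frames/s over a ≤ 4 s window): the participant starts at
rest, self-paces into the movement, and holds it until the trial ends.
Under this protocol the first frame is the resting muscle configuration and
the final frames carry the held, movement-specific tissue deformation. The
pipeline therefore works with two summary *muscle states* per trial:

* **initial state** — the first frame's masked pixel vector;
* **end state** — the element-wise mean of the last `end_state_frames`
  (default 5) frames' masked vectors.

All dissimilarities are Pearson: d(a, b) = 1 − r(a, b) ∈ [0, 2]. We read
"Pearson dissimilarity" literally rather than 1 − |r| or 1 − r²:
anticorrelated states are maximally dissimilar (d = 2). d is symmetric,
zero on identical inputs, invariant under positive affine rescaling of
either argument, and undefined (an error) for zero-variance vectors — a
zero-variance state always indicates a degenerate input upstream, not a
quantity to be silently patched.

### Preprocessing

Frames are block-mean downsampled (each output pixel is the unweighted mean
of its source block; requires divisible shapes). Block means are
deterministic, interpolation-free, and preserve the global mean intensity.
A per-limb **static-pixel mask** then keeps a pixel iff, in at least one
trial, some frame differs from that *trial's first frame* by more than
`static_pixel_tolerance` (default 0, exact non-deviation). The per-trial
reference resolves an ambiguity in the filter's verbal definition (initial
value *per trial* vs one global initial value); the per-trial reading is
the weaker condition and never masks genuinely active pixels. The mask is
built from one limb's trials only, so classification and RSA share a single
feature space per recording block; it is persisted as (row, col)
coordinates in CSV.

### Classification

k-nearest neighbours under d with majority vote; default k = 1 (with only
4–9 training examples per class, larger k rapidly exhausts the class;
k is configurable and recorded in provenance). Tie-breaking is fully
deterministic: distance ties resolve by training order (stable sort), vote
ties by the tied class whose nearest member is closest, then by the fixed
class order. Leave-one-out cross-validation classifies every end state
against all others and accumulates a 6×6 confusion matrix in fixed class
order. Summaries: accuracy (trace/total), per-class true-positive rate
(diagonal/row sum), and the number of movements at TPR ≥ `ca_threshold`
(default 0.80 — one error in a five-trial movement sits exactly at the
threshold).

Chance level is reported as 1/6 ≈ 16.7%. Note one subtlety: under *label
permutation* (rather than i.i.d. relabeling) the expected LOOCV accuracy is
(m − 1)/(n − 1) for m trials per class out of n — 15.3% for m = 10, 13.8%
for m = 5 — slightly below the nominal 1/6 because the held-out trial's
label cannot coincide with itself. The empirical chance test uses 10 trials
per class, where the two figures agree within two percentage points.

### Split-data RDM, EDI, and the exhaustive randomization test

Each movement's trials are split in half — default **contiguous** (first
⌈n/2⌉ trials in acquisition order vs the rest), which leaves the diagonal
sensitive to slow session drift; a seeded random split is available.
sdRDM(i, j) = d(half-A mean of movement i, half-B mean of movement j). The
matrix is generally asymmetric with a nonzero diagonal: the diagonal is the
cross-split dissimilarity of the *same* movement, i.e. an estimate of the
within-movement noise.

EDI = mean(30 off-diagonal entries) − mean(6 diagonal entries). Means, not
sums: means are the convention of the RSA literature the index comes from
and make the statistic independent of the number of conditions; a
sum-based variant differs only by the fixed factors 30 and 6.

Significance: with six movements there are exactly 6! = 720 permutations
of one split's labels (equivalently, row permutations of the sdRDM), so the
null is enumerated exhaustively rather than sampled. The p-value counts
null values ≥ the observed EDI *including the identity permutation*, so
p ≥ 1/720 always — a valid randomization test can never report p = 0. Row
permutation of one split is the literal reading of the test; permuting
rows and columns independently would correspond to relabeling both splits
and gives a different (larger) group, which we do not use.

### Cross-limb comparison

Movement RDMs use whole-set means (symmetric, zero diagonal). Relatedness
between limbs is the Pearson correlation of the 15 upper-triangle entries
only — including the six structural zeros of the diagonal would inflate
the correlation. The null applies each of the 720 label permutations
simultaneously to rows and columns of one limb's RDM (a relabeling of that
limb's movements) and recomputes the correlation; p as above.

### Trajectory geometry

For one limb, every frame of every trial is a point; the all-frames
Pearson dissimilarity matrix is embedded with classical (Torgerson) MDS:
double-centre the squared dissimilarities, eigendecompose, scale the top-d
eigenvectors by √eigenvalue. Classical MDS is deterministic (no random
initialization). Pearson dissimilarities are not guaranteed Euclidean;
negative eigenvalues are truncated to zero and their total magnitude is
reported (for large frame sets, where only the top-d eigenpairs are
computed via Lanczos iteration, that diagnostic is NaN). Stress is the
normalized RMS error between input dissimilarities and embedded Euclidean
distances.

The **trajectory-separation index** is an added quantitative summary, not
part of the original qualitative analysis: for each movement pair, over the
embedded frames of the final `hold_fraction` (default 0.25) of each trial,

    (between-centroid distance − mean within-movement spread)
        / max(between, within),      with 0/0 := 0.

Positive values mean the two movements' held end regions are spatially
distinct; a compensatory strategy that reaches "different" movements along
one shared path would collapse the index toward zero.

## The synthetic generator

The generator emulates the recording protocol, not ultrasound physics. Per
limb: a smooth resting intensity field (broad seeded Gaussian bumps over a
base level of 100, clipped nonnegative), one deformation prototype per
movement (rest + 6 isotropic Gaussian bumps, width min(size)/12, signed
amplitudes 40 × U(0.6, 1.4), seeded positions), and trials

    frame(t) = rest + s(t) · a · (proto − rest) + ε(t)

with s(t) a logistic ramp (midpoint 2 s, steepness 5 s⁻¹) normalized and
clamped so s(0) = 0 exactly and s(t) = 1 exactly for the final 0.5 s;
a ~ N(1, 0.1²) per-trial amplitude jitter; ε i.i.d. N(0, σ²) pixel noise.
A `static_margin` border (default 4 px) carries neither deviation nor
noise, emulating screen regions without image data and exercising the
static-pixel filter. Cross-limb structure is controlled by the shared
weight w: affected deviations are w · (unaffected deviation) + (1 − w) ·
(independent deviation); w = 1 duplicates the structure, w = 0 makes it
independent. The w → expected-RDM-correlation map is calibrated
empirically (see the recovery tests), not claimed analytic. A null variant
gives all six movements one prototype, making the labels exchangeable by
construction.

Defaults define the emulated study conditions: 6 movements × 5 trials ×
2 limbs (five trials is the guaranteed first block of the protocol; designs
with up to 10 trials per movement are supported and tested), 120 frames at
30 frames/s over 4 s, raw size 256×256 (a `--full-size` flag generates the
nominal 1024×1024; the downsampler logic is identical). Pixel noise
defaults to σ = 100 against blob amplitudes of ~40: this places the
pipeline in the realistic regime where the sdRDM diagonal is clearly
nonzero and EDI lands around 0.2–0.4 while LOOCV accuracy stays above the
80% reliability threshold. σ sweeps up to 500 are used to exercise
monotone degradation (accuracy falls toward chance), and σ = 20 serves as
the "low noise" condition of the structure- and trajectory-recovery
experiments.

What the generator does **not** model: speckle statistics, acoustic
shadowing, probe motion, anatomical deformation fields, or trial-to-trial
*structured* motor variability (its only within-movement variation is
amplitude jitter plus i.i.d. noise). Passing recovery tests therefore show
the estimators are correct and calibrated under the stated generative
model — they do not certify performance on real ultrasound, where
within-movement variability is structured and masks are far sparser.

## Problem sizes and numerical choices

The test and acceptance experiments run at reduced image sizes chosen as
the package's own benchmark scale: raw 64×64 (downsampled 32×32, ~784-pixel
feature vectors after masking — the same order as the ~1000-pixel vectors
of real recordings) for per-subject checks and null calibration, and raw
32×32 (downsampled 16×16) for the large replicate sweeps (100 seeds per
shared-weight level, 500 null replicates, 50 start-vs-end seeds). Frames
are generated and stored as float32. Correlations are clipped to [−1, 1]
before forming distances; distance matrices are symmetrized explicitly to
remove float asymmetry; the permutation tests take the observed statistic
from the enumerated null array itself so the p ≥ 1/720 guarantee is exact
in floating point. Classical MDS uses a full eigendecomposition up to
n = 1200 and ARPACK top-d beyond.

## Known limitations

* The six-movement class order is fixed package-wide; confusion matrices
  and RDMs always carry all six classes, and analyses require ≥ 2 trials
  per present movement (LOOCV and splitting are undefined below that).
* The EDI permutation test's 720-way null is specific to six conditions;
  other condition counts enumerate n! permutations, which is only practical
  for small n.
* With heavy noise, a 3-D MDS projection of six near-equidistant movement
  clusters can overlap for individual pairs even when the full-space
  dissimilarities are large (six equidistant points require five
  dimensions); the separation index is therefore read jointly with the
  embedding stress.
* Manual trial exclusion (video review) is supported only as an exclusion
  list applied at load time; no automatic artifact detection is attempted.
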