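# Methods

## The model

CMSFL-Net is a compact convolutional classifier for small labeled image
sets (small sides, few samples per class, possibly imbalanced classes). Its
building block learns multiscale features *consecutively* rather than in
parallel: a main branch (MB) of four Conv(3×3)–BN–ReLU units deepens stage
by stage, while at stages 2–4 a secondary branch (SB) applies a fresh 3×3
convolution to the *unpooled block input* and concatenates it channel-wise
onto the main-branch output:

    u1 = CBA(mb1, x)
    u_k = [ CBA(mb_k, u_{k-1}) | CBA(sb_{k-1}, x) ]      k = 2, 3, 4

Each stacked 3×3 convolution grows the receptive field (RF) by 2, so the
block's channel groups expose the RF set (9, 7, 5, 3) after stage 4. The
concatenation keeps low-RF information from the original input alive next
to progressively more abstract features — a counterweight to the
information loss that 2×2 max-pooling inflicts between blocks.

The cost argument is combinatorial: reaching the RF set (2k+1, …, 5, 3)
consecutively takes 2k−1 convolutions (one at stage 1, two per later
stage), versus k(k+1)/2 for a traditional multiscale stack that rebuilds
every RF independently — 7 versus 10 at k = 4. Per filter, the consecutive
block spends 7·3² = 63 weights where single-kernel multiscale sets spend
3²+5²+7²+9² = 164 (or 204 with an 11×11 top kernel). The `accounting`
module makes this ledger exact, including per-layer trainable parameters
(ks²·c_in·c_out, plus 2 per channel for BN gain/bias; running statistics
are not trainable and are excluded) and multiply–accumulate FLOPs
(IV_H·IV_W·c_in·ks²·c_out). The ledger is tested against an exhaustive
element count of a built network's parameter archive, not against a second
formula.

The full network stacks N blocks (default 6, studied sizes 4/6/8/10), each
followed by 2×2 max-pooling, and ends in a bias-free head: either a dense
map on the flattened features or (default) a cosine-normalized head that
scores each class by a learned scale α times the cosine between the feature
vector and that class's weight vector. Cosine normalization removes the
magnitude advantage that over-represented classes build up in their weight
vectors, which matters on imbalanced sets. The constraint
`input_side ≥ 2^N` keeps pooling from collapsing below one pixel; at the
default 64px / 6 blocks, the head input is exactly 2F = 64 features.

## Objective and metrics

Training minimizes the class-weighted categorical cross-entropy
L = −(1/M) Σ_j Σ_i ω_j y_i^j log p_i^j with probabilities clamped at 1e−12.
Three weight sources are selectable: `uniform`; `inverse_frequency`
(ω_j ∝ 1/count_j, normalized to sum to J — the default, the conventional
remedy that up-weights rare classes); and `cosine_softmax` (the softmax of
scaled cosine similarities, the cosine-classifier output itself read as a
weight vector). The direction of a principled imbalance correction is
ambiguous in the surrounding literature — some formulations up-weight rare
classes, some down-weight them — so both readings stay available and none
is applied silently: the engine's default is inverse-frequency.

Evaluation reports AS (fraction of correctly classified instances) and
macro-F1 (unweighted mean of one-vs-rest F1; the binary F1 formula extended
to multiclass by macro-averaging). Classes absent from both predictions and
truth contribute F1 = 0 and are flagged.

## Preprocessing and the inference contract

The pipeline order is fixed: tensorize → resize (bilinear) → standardize →
augment. Standardization subtracts the grand mean and divides by the
population standard deviation of the **training** batch, pooled over all
M·C·H·W entries (a global scalar; a per-channel variant sits behind
`fit_stats(..., per_channel=True)`). Validation, test and inference data
are standardized with those same training statistics. This contract is
enforced structurally: `predict` compares a SHA-256 digest of the supplied
statistics against the digest stored with the trained parameters and
refuses a mismatch. The inference path is exactly resize ∘
standardize(train stats) — augmentation never runs there.

Augmentation draws from four affine families — rotation, anisotropic
scaling, X-mirroring, axis swap — expressed as 3×3 homogeneous matrices.
They are applied about the image center (origin-anchored rotation would
push content off-canvas) with bilinear sampling and constant fill 0, which
is the neutral value after standardization. Matrices act on sampling
coordinates; mirroring and axis swap are exact involutions at the pixel
level because the center maps integer columns to integer columns. The
default policy (rotate ±15°, scale 0.9/1.1, mirror, axis swap, each with
probability 0.5) appends copies and returns a source-index vector so label
vectors grow in lockstep.

## Training

The implementation is pure NumPy. Convolution is expressed as nine shifted
slab GEMMs — one per kernel tap, each a contiguous view of the padded input
multiplied by an (F, C) weight slice — which keeps everything in BLAS with
no im2col patch buffer; the backward pass (data, weight and BN gradients)
is hand-written and verified against central differences to ~1e−8 relative
error. Adam is used with learning rate 1e−4, first-moment decay 0.9 (γ is
read as Adam's β₁ — Adam has no classical momentum term), second-moment
decay 0.999 and ε = 1e−8; the last two are unstated by the design and
fixed at their conventional values. Weights are He-initialized Gaussians
(sd √(2/(9·fan_in)), matching the ReLU activations); convolutions and
heads carry no bias; BN uses ε = 1e−5 and running-statistic momentum 0.1.
Defaults: 50 epochs, mini-batch 64 below a 96px side and 16 at or above it
(the small/large-scale boundary is not pinned anywhere, 96 is this
package's choice). There is no learning-rate schedule or weight decay; the
best-validation-AS epoch is checkpointed as plumbing. With fixed seeds the
whole pipeline — generation, splitting, batching, initialization — is
bit-reproducible on CPU.

## The synthetic generator

Real benchmark images are replaced by a generator that emulates only the
*statistical regime* of small classification datasets: class count, counts
per class (imbalance as exact counts, so inverse-frequency weights are
testable against arithmetic), image side, and a difficulty dial. Each class
renders a motif family — oriented sinusoidal gratings, fixed blob
constellations, or rings of a class-specific radius — chosen because each
is discriminable by small receptive fields, matching the 3×3-kernel design.
Per-image jitter (phase, sub-pixel center shifts) keeps classes
non-degenerate; `difficulty` blends every class toward a neutral gray
canvas, and additive Gaussian noise (default sd 0.05) is clipped to [0,1].
At difficulty 0 a nearest-class-mean classifier exceeds 0.9 held-out
accuracy (the learnability floor is checked by that independent oracle, not
by the network); at difficulty 1 with noise sd 0.5 the same oracle is at
chance. What passing tests show is therefore that the pipeline can learn
cleanly separable low-level structure end to end; they say nothing about
photorealistic CT/MRI/histopathology texture, covariate shift, or label
noise, none of which the generator models.

Splits are stratified per class with largest-remainder allocation
(guaranteeing every nonzero fraction at least one sample per class) and are
exact partitions — disjointness and union are property-tested.

## Problem sizes in the checked-in runs

The test suite and the acceptance script run entirely on generated data at
desk scale: the end-to-end run trains the default 6-module, F = 32 network
on 120 training images (3 balanced classes, 64px) without augmentation,
stopping once eval-mode training accuracy reaches 0.97 (at most 20 epochs;
typically 5–7). Unit and property tests use 2–4-module networks with 4–8
filters at 16px. Ablation over 8–10 modules requires sides of 256–1024px
and is exposed through `run_ablation`/`cmsfl ablate` but not exercised in
tests at that scale.

## Numerical choices and edge cases

- Probability clamp 1e−12 before logarithms (configurable constant).
- Zero-variance batches are rejected at `fit_stats` (standardization
  undefined) rather than producing infinities.
- Arg-max ties in `predict` resolve to the lower class index.
- `max_pool` requires even sides; the network config invariant makes the
  condition unreachable in assembled models.
- The parameter-count ledger counts ks² weights per filter in P_tr; a
  literal single-ks reading is inconsistent with the FLOP line and with the
  per-filter weight sums above, so the squared form is used in both.
- A 4-deep 3×3 stack has RF 9, so the ledger reports 9×9 as the
  single-kernel equivalent of the four-stage set; the 11×11 variant of the
  weight-sum comparison (204) is computed alongside the 9×9 one (164) by
  `stacked_weight_sum`.
- SB units do not share parameters across stages (three independent convs
  are what the seven-conv count implies), and concatenation order is frozen
  as [MB | SB] for reproducibility.

## Known limitations

- CPU-only NumPy: throughput is adequate for desk-scale experiments
  (seconds per epoch at 64px × 150 images) but not for real benchmark
  training.
- The published parameter totals for the 4/6/8/10-module variants
  (0.56/0.86/1.17/1.49 M) are not recoverable from "32 filters everywhere"
  plus any head the figures imply; per-module width overrides are a
  possible extension, but this package does not guess the original widths
  and its ledger reports what the implemented architecture actually
  contains (0.65 M at 6 modules, 3 classes).
- `global_avg` head and non-studied module counts are provided for
  exploration; only the flatten head and 4/6-module configurations are
  exercised by the test suite.
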