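# Methods

## Problem and model

`ordvert` targets ordinal image classification: assigning each axial CT-like
slice to one of N ordered anatomical levels (T12 < L1 < L2 < L3 < L4 in the
motivating vertebral-level task, N = 5). Plain cross-entropy (CE) treats the
levels as unordered — predicting T12 for an L4 slice costs the same as
predicting L3 — so the package centres on the **ordinal residual dual loss
(ORDL)**, which augments CE with a penalty that grows with rank distance.

For a true class c among N classes, define the target probability profile

    O_i = 1 − |i − c| / (N − 1),

a vector with peak 1 at the true class, decaying linearly to 0 at rank
distance N − 1. O is deliberately not a normalised distribution; it is a
per-class target. With predicted probabilities P (softmax output) and
residuals d_i = P_i − O_i, the ordinal residual loss is

    ORL(P, c) = − Σ_i log(1 − |d_i|),

and the dual loss is ORDL = CE + λ·ORL with λ = 1 by default (an unweighted
sum; λ is exposed for sensitivity analyses). Each term of ORL is zero exactly
when the predicted probability matches its target and grows without bound as
|d_i| → 1, so probability mass placed far from the true class is penalised in
proportion to how badly it violates the decaying profile.

**Residual sign.** Written literally with signed residuals, log(1 − d_i)
exceeds zero when a class is under-predicted (d_i < 0), i.e. the loss would
*reward* under-prediction and could go negative. We therefore use |d_i|; the
signed variant remains available behind `signed=True` for fidelity
experiments. ORL is not normalised by N (no normalisation is part of its
definition); loss magnitudes are therefore only comparable at fixed N.

**Clamping.** 1 − |d_i| = 0 is reachable (P_i = 1 where O_i = 0), as is
P_c = 0, so all log arguments are clamped at ε = 1e−12. Every loss is finite
and non-negative.

## Baselines

* **CDW-CE** — class-distance-weighted CE, −Σ_i |i − c|^a · log(1 − P_i).
  The true-class term carries weight 0 (|c − c|^a with the 0^0 corner is
  resolved by excluding the term: a perfect one-hot prediction scores 0).
  The exponent a must be tuned by hand, and large a destabilises training —
  the behaviour the dual loss is designed to avoid.
* **CORN** — N − 1 binary tasks estimating P(y > k | y > k − 1), trained on
  chained conditional subsets (task k sees the samples with label ≥ k) with
  binary cross-entropy. The total is normalised by the number of contributing
  (sample, task) pairs rather than by task count, so tasks with tiny
  conditional subsets do not dominate. Unconditional rank probabilities are
  cumulative products, which are non-increasing for any input — rank
  consistency by construction. Decoding counts chained probabilities strictly
  greater than 0.5.
* **CORAL** — provided as a reference head only (shared score g plus per-task
  biases, σ(g + b_k); monotone whenever the biases are sorted descending).
  It is not a benchmarked training method here.

CE/ORL/ORDL/CDW-CE consume a softmax head of size N; CORN uses a sigmoid
binary-task head of size N − 1. Class indices are 0-based throughout; rank
decoding from binary-task probabilities uses strict "> 0.5", with exact ties
counting as "not greater".

## Metrics and the primary comparison

Accuracy, macro F1 (averaged over all N classes; a class absent from both
truth and prediction contributes F1 = 0 and still counts), MAE and RMSE on
rank indices, and quadratic weighted kappa (weights (i − j)²/(N − 1)²). The
probability-ordering consistency check walks outward from a reference class
(the true class when known, else the argmax with ties toward the lowest
index) and flags any step where a farther class has strictly higher
probability than its nearer neighbour.

Method comparison uses Welch's unequal-variance two-sample t-test on fold
accuracies, two-sided, with Welch–Satterthwaite degrees of freedom, at
α = 0.05. The CE-vs-ORDL contrast is pre-specified as primary; all other
pairs are reported descriptively (mean ± SD) without inferential testing.
Folds are paired: every method trains on byte-identical fold data, with
per-fold model/shuffling seeds derived deterministically from (base seed,
fold index, loss name).

## Data protocol

Splitting is by **patient count**, never by image: with 84 patients at ratio
0.8, `floor(0.8·84) = 67` patients train and 17 test, and ten-fold CV
partitions the 67 training patients into folds differing in size by at most
one (7×7 + 3×6), each fold serving once as the validation set that drives
early stopping. The held-out test patients are untouched by model selection.

Preprocessing: (1) crop maximal black borders (threshold 2 % of the image
maximum — a tolerance is needed for noisy margins); (2) resize with a single
scale factor on both axes (no aspect distortion); (3) pad symmetrically with
zeros to the exact target size; (4) min-max normalise to [0, 1] (the
convention of the desk-scale CNN; backbone-specific affine normalisation can
be substituted). Images are stored as 8-bit grayscale PNG with a CSV
manifest; the first write quantises to 256 grey levels, after which
round-trips are exact.

## Training harness

Adam (betas 0.9/0.999), learning rate 1e−4 (1e−5 for CDW-CE, which otherwise
tends to diverge at larger exponents), batch size 8, L2 weight decay 1e−4,
early stopping on validation loss with patience 10 within max 1000 epochs,
restoring the best-epoch checkpoint before evaluation. A non-finite training
or validation loss aborts the run, which is reported as NaN/failed and
excluded from means — never silently dropped.

The trainable model is a deliberately small CNN — three conv(3×3)/ReLU/
max-pool(2×2) blocks (8, 16, 32 filters) and a linear head — implemented in
NumPy with hand-written backpropagation (im2col convolutions, analytic loss
gradients chained through the softmax/sigmoid heads). Gradient correctness is
verified against central finite differences in the test suite. Any model
honouring the same contract (image batch → logit batch of arity N or N − 1,
gradient updates from dL/dlogits) can be plugged in.

## Synthetic cohort generator

Real vertebral CT data is private, so the generator emulates its *structure*:
`n_patients` patients × `n_levels` levels × 4–6 slices per level (drawn
uniformly), grayscale images in [0, 1]. Each slice contains a bright
elliptical vertebral-body stand-in with two flanking lateral structures;
level identity is encoded geometrically — vertical position, (slightly) body
radius, and flanking offsets all shift monotonically with level — so
convolutional models face a spatial, not merely intensity, signal and
adjacent levels genuinely look more alike than distant ones. A per-patient
Gaussian effect (sd `patient_effect_sd`) jitters the whole geometry coherently
across a patient's slices, inducing the within-patient correlation that makes
patient-level splitting the honest protocol. Pixel noise is i.i.d. Gaussian
(sd `noise_sd`), clipped to [0, 1]. All randomness flows from one seeded
generator; identical configs give bit-identical cohorts.

Defaults: 84 patients, 5 levels, 64×64 images, `level_separation` 0.15 (as a
fraction of image height per level step), `noise_sd` 0.05 — i.e. separation
three times the noise sd, a strong ordinal signal — and `patient_effect_sd`
0.03. The motion coefficients are scaled so that at the default separation the
extreme levels' ellipses still overlap; this keeps mean pixel-space distance
increasing with rank distance (verified by `cohort_difficulty_profile`)
instead of saturating once shapes disengage.

What the generator does **not** emulate: Hounsfield-unit physics, scanner
artefacts, anatomical variation beyond smooth geometric jitter, class
imbalance, or label noise. Passing the end-to-end tests therefore shows the
pipeline and losses behave correctly on a clean ordinal signal, not that any
accuracy level transfers to clinical CT.

## Scaled-down experiment sizes

The shipped end-to-end comparison uses a 40-patient cohort (≈1000 slices),
model inputs preprocessed to 32×32, and max 120 epochs — patience-10 early
stopping converges far earlier on the synthetic signal, typically within
20–40 epochs — with 10-fold paired CV of CE vs ORDL. These are the package's
desk-scale study conditions; the protocol constants (patience, batch size,
weight decay, learning rates) are unchanged from the full-scale protocol.
The directional expectation that ORDL's mean MAE not exceed CE's is logged in
the report and raised as a warning when violated; being a stochastic claim at
n = 10 folds, it is not a hard assertion.

## Known limitations

* The NumPy CNN is CPU-only and desk-scale; absolute accuracies from the
  synthetic benchmark are not comparable to published clinical results.
* ORL treats probabilities independently per class (no simplex coupling
  beyond the softmax); its minimiser over the simplex generally differs from
  O itself since O sums to more than 1 for N > 2.
* QWK is returned as 0 with a warning when the agreement table is degenerate
  (e.g. constant identical labels on both sides).
* Welch's test on 10 paired folds has limited power; the harness reports the
  test as specified rather than claiming calibrated error rates under CV
  dependence.
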