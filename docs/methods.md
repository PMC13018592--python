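# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish.

## Network

Each residual block applies, in order: 3×3 same-padded stride-1
convolution → batch normalization → ReLU → skip addition → dropout → 2×2
max pooling. No activation follows the addition. The skip path is the
identity when input and output channel counts match, and a 1×1 projection
convolution otherwise; in the pinned configuration (1 input channel, five
blocks of 128 channels) only block 1 projects. The head is adaptive
average pooling to 2×2, a flattening, a 128-d fully connected layer with
linear activation (the raw latent is kept for downstream use), and a
2-class softmax. Trainable parameters — convolution and linear weights
and biases plus batch-norm scale/shift, excluding running statistics —
total 659,074 (= 1,792 + 4·147,840 + 65,664 + 258), i.e. 0.66 M.

The engine is pure NumPy: convolution by im2col + matmul with an explicit
col2im backward, batch-norm with training/inference modes, inverted
dropout with a per-call rate (so the training rate and the Monte-Carlo
inference rate are independent), max pooling with first-maximum
tie-breaking, and torch-style adaptive-average-pool binning
(`[floor(iH/S), ceil((i+1)H/S))`). The backward pass serves both training
and Grad-CAM, and was verified against central finite differences. Class
convention: stroke is index 0 (the positive class), normal is index 1.

Training uses cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999), seeded
shuffling and He-uniform initialization, retains the best-validation-loss
weights, and early-stops after a patience of epochs without improvement.
Defaults (lr 1e-3, batch 32, patience 10) are ordinary choices; the test
fixtures use lr 3e-3 and batch 16, which converge faster at their small
scale. Training is bit-deterministic given the seeds.

## Uncertainty

`mc_predict` runs N stochastic passes with dropout active at rate p
(batch norm stays in inference mode), averages the softmax outputs, and
computes the normalized entropy H = −Σ p log p / log C. The division by
log C pins the range to [0, 1] for any class count, with the uniform
distribution at exactly 1 — for two classes this is Shannon entropy in
bits. Seeding: each (seed, image index, pass index) triple spawns an
independent substream, so pass n is identical whatever the total N; sweeps
over ensemble size are therefore nested, and the N = 1 row of a sweep is
exactly the single-pass prediction.

Dropout-rate calibration scores each grid value by rank discrimination:
the probability that a misclassified validation sample's entropy exceeds a
correctly classified one's (ties half; equivalently the AUC of H as a
misclassification detector). Correctness is judged against the MCD mean
prediction at that same rate. Ties break toward smaller p; if no rate
produces any misclassification the smallest rate is selected and a warning
recorded. The default ensemble size is N = 20; accuracy saturates around
N = 10 in our sweeps, so 20 sits inside the plateau, and the cheaper
test-suite checks use 8–10 passes for the same reason.

The rejection rule is `reliable iff H ≤ α` (inclusive), with α the mean
entropy of the validation set at p\*. Computing α on validation rather
than on the incoming batch avoids test-time leakage and gives a fixed,
auditable threshold.

## Saliency and the correction rule

Grad-CAM targets the last residual block's convolution output: channel
weights are spatial means of the class-score gradient, the weighted sum is
ReLU-clipped, bilinearly upsampled to the input size, and min-max
normalized; a constant raw map normalizes to all-zeros (MSI 0) rather than
dividing by zero. Grad-CAM++ uses the standard second/third-order gradient
weighting; Score-CAM weights each activation channel by the class-score
increase over a blank baseline when the input is masked by the normalized,
upsampled channel. MCD-mode saliency normalizes each per-pass map,
averages over N passes, and renormalizes — every pass contributes on an
equal footing; with p = 0 the passes are identical and the deterministic
map is returned bit-exactly.

MSI is the plain mean of the normalized map. The correction threshold
D = min(max MSI over validation true positives, max MSI over validation
true negatives); retained predictions with MSI strictly above D are
flipped to the other class (equality keeps — the conservative reading of
the overlapping ≥/≤ rules, minimizing interventions).

Two choices here were genuinely open and were settled by experiment:

* **Explained class for the MSI rule.** The maps that feed the threshold
  and the flip all explain the *stroke* class — the hypodensity-evidence
  map — for every sample, rather than each sample's own predicted class.
  Maps explaining "normal" are ReLU-dominated and near-zero (MSI ≈ 0.04
  in our runs) while stroke maps average ≈ 0.4; with per-prediction
  classes the two outcome groups live on incommensurate scales, the min()
  in the threshold collapses to the near-zero group maximum, and the rule
  flips essentially every confident true positive. One fixed class keeps
  all MSI values comparable, which the min() construction presumes.
  `saliency_map` itself still defaults to explaining the model's
  prediction, the standard convention for visualization.
* **Fitting-set size.** D is a sample maximum, so it is only stable with
  dozens of TP and TN validation cases; with ~25 validation images the
  fitted D sits inside the bulk of the test MSI distribution and the rule
  fires on half the test set. The shipped defaults and examples fit D on
  ~100 validation phantoms. On our phantoms the calibrated rule then
  fires rarely and is roughly accuracy-neutral — consistent with its role
  as a backstop for diffuse-attention errors rather than a second
  classifier.

D is fitted on validation outcomes (where TP/TN status is known) and
applied at test time to every retained sample, since misclassification
status is unknowable at inference.

## Evaluation

Metrics are percentages with 95% Wilson score intervals
(z = Φ⁻¹(0.975) ≈ 1.959964); degenerate proportions (0/n, n/n) clamp the
corresponding bound exactly to 0 or 1. A zero-denominator metric is
reported as undefined (NaN), never as 0. Abstained (flagged) samples are
excluded from the confusion counts and tallied separately, and reports are
offered both retained-only and with abstentions counted.

MoRF curves rank pixels by saliency (descending, row-major tie-break via
stable sort), replace the top fraction f ∈ {0, 0.05, …, 1} with the
dataset mean intensity (zero replacement available), and track the
deterministic softmax confidence of the originally predicted class; the
f = 0 point is bit-exactly the unperturbed confidence. AUPC is the
trapezoidal area over the unit square (so AUPC ∈ [0, 1]); a grid-sum
variant is also exported for comparability with conventions that sum
per-step confidences. Method selection is argmin AUPC with ties toward
Grad-CAM.

Calibration: ECE/MCE over 10 equal-width confidence bins (empty bins
skipped; the bin gap is |accuracy − mean confidence|), Brier as the
binary positive-class squared error. Temperature is fitted on validation
logits by bounded scalar NLL minimization over T ∈ [0.05, 20] (tolerance
1e-5); monotone scaling leaves argmax predictions unchanged.
Risk–coverage sweeps thresholds over the observed entropy values plus
{0, 1}: coverage is the fraction with H ≤ t and risk is 1 − accuracy
among the covered (undefined at zero coverage).

## Phantoms

A phantom is a square [0, 1] image: air background 0.05, a skull annulus
at 0.95 (outer 6 % of the radius), parenchyma at base 0.5 with a
Gaussian-smoothed random texture (σ_texture 4 px, amplitude 0.03,
clipped to [0.4, 0.6]), and — for the stroke class — one hypodense blob.
The blob is a disk of radius `lesion_radius_frac × brain radius` whose
edge is softened by blurring a 2σ-dilated disk (σ_edge = max(1, 0.15 r)),
so that the mean decrement inside the binary ground-truth mask matches
`lesion_contrast` to within ~1 %. Lesion geometry is drawn from the RNG
stream regardless of label, so a stroke phantom and a normal phantom from
the same parameters are a matched pair differing only by the lesion.
Additive Gaussian noise (σ ∈ [0, 0.1]) and clipping come last.

The default difficulty mix is 60 % easy (contrast 0.15–0.25) and 40 %
hard (contrast 0.03–0.08, near the noise floor at the default σ = 0.03):
this guarantees both confident and genuinely ambiguous cases, so the
rejection and flip rules have real work. Parameter ranges
(contrast ∈ [0.02, 0.3], radius fraction ∈ (0, 0.5], noise ∈ [0, 0.1])
are enforced. Datasets are persisted as 8-bit PNGs (pixel = round(255 v))
for inspection plus a lossless npz bundle for bit-exact round trips, with
a CSV manifest and JSON parameter sidecar. Splits follow the requested
fractions by largest-remainder allocation, stratified by label.

**What the phantoms do not show.** They are 2-D cartoons: no anatomy, no
partial-volume or beam-hardening artifacts, no slice-to-slice correlation,
no patient-level structure, and a single lesion per image. Passing tests
demonstrate that the pipeline's machinery behaves as specified — entropy
rejection retains a more accurate subset, saliency localizes the
hypodensity, perturbation curves rank methods — not that any accuracy
level transfers to clinical CT.

## Problem sizes

The test suite and examples train a three-block 8/16/32-channel variant on
200 phantoms of 48 px (≈ 9 k parameters, ~40 s to train) and run the
stochastic analyses with 8–10 passes; behavioural properties that compare
stochastic quantities are decided by majority over five seeds. The pinned
five-block/128-channel architecture is instantiated for parameter
accounting and available for full-scale runs via the CLI. These sizes are
the package's own test-scale choices; every operation accepts the
full-scale settings.

## Known limitations

* The NumPy engine is single-threaded matmul-bound; the full 224-px,
  128-channel configuration trains orders of magnitude slower than a GPU
  framework would. The architecture is faithful; the speed is not the
  point.
* Small, confidently overfit phantom models yield flat MoRF curves (high
  AUPC for every method); the *ordering* of methods remains informative
  and is what the tests assert.
* The MSI flip rule is a blunt instrument: on phantoms its calibrated
  form is nearly inert, and the package deliberately reports it that way
  rather than tuning it into activity.
* Aleatoric uncertainty, deep ensembles, Bayesian layers, multiclass
  staging, 3-D volumes, and DICOM ingestion are out of scope.
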