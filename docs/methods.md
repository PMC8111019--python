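# Methods

## The problem and the approach

Pneumothorax (air in the pleural space collapsing a lung) is an emergency
finding on frontal chest radiographs with a notoriously low visual detection
rate. Instead of training an end-to-end classifier, `thoraxsearch` treats an
archive of already-diagnosed radiographs as the model: every archived image
is tagged with a fixed-length descriptor, a query image is matched against
the archive by Euclidean distance, and the fraction *m/k* of positive labels
among its *k* nearest neighbours is the class likelihood. Retrieval returns
the matched cases themselves, so the output is auditable in a way a bare
probability is not.

Three descriptor configurations exploit thoracic bilateral symmetry:

1. the whole radiograph → one 1,024-d vector;
2. the left half plus the horizontally flipped right half →
   `[left, right_flipped]`, 2,048 values;
3. both halves plus the whole image → `[left, right_flipped, whole]`,
   3,072 values.

Flipping the right half is a coarse registration: both hemithoraces are
presented to the extractor in the same orientation, so a one-sided pleural
abnormality shows up as a *difference between two otherwise comparable
segments* of the concatenated vector.

## The frozen backbone

The extractor is a pluggable contract: any deterministic map from a
224 × 224 × 3 image to a constant-length vector. The conventional choice is
the global-average-pooled final convolutional layer of a DenseNet-121-class
network (1,024 values). The package's default is a `StubBackbone` — per-channel
mean pooling over 32 × 32 blocks (7 × 7 × 3 = 147 values) followed by a fixed,
seeded Gaussian projection to 1,024 — chosen because it is pure arithmetic:
exactly reproducible on any machine, no weight files, and linear, so the
symmetry properties of the views carry through to the descriptors exactly.
Everything downstream of the backbone is agnostic to which extractor
produced the store.

## The two-step compressor

Long concatenated descriptors are compressed 12× (3,072 → 256) before
search:

* **Step 1, unsupervised:** a symmetric autoencoder (decoder mirrors the
  encoder widths) is trained to reconstruct its input — mean squared error,
  Adam (learning rate 1e-3), batch size 128, 10 epochs, inverted dropout at
  rate 0.2 after every non-final layer.
* **Step 2, supervised:** the decoder is removed, a single sigmoid unit is
  attached after the bottleneck (dropout between code and head), and the
  whole encoder plus head is trained for 10 more epochs with class-weighted
  binary cross-entropy. The per-class weight is `W_c = S / (C · S_c)`
  (S total samples, C classes, S_c in class c), which gives every class the
  same total loss mass `S / C` regardless of imbalance — at 6% prevalence the
  positive class is upweighted ≈ 8×.
* The head is then removed; the remaining encoder is the deterministic code
  map used for both archive and queries.

Implementation is a compact dense network on NumPy (explicit forward/backward
passes, Adam with bias correction). Design choices where the procedure is
genuinely open:

* **Hidden activations** are ReLU on intermediate layers; the **bottleneck is
  linear** (codes are unrestricted reals — a ReLU bottleneck of width exactly
  equal to the signal dimension could not even represent a centred linear
  subspace), and the reconstruction output is linear.
* **Default widths** are `[3072, 1024, 512, 256]` with a mirrored decoder
  (geometric tapering; configurable). The synthetic benchmark uses the slimmer
  `[3072, 512, 256]`, which reaches the same bottleneck at a fraction of the
  training cost.
* **Validation split:** 10% of the training archive, held out by seed, used
  only to record a validation loss curve. The final-epoch weights are always
  kept; there is no early stopping.
* The final-epoch convention, batch size 128, dropout 0.2, Adam, and the
  10-epoch budget per phase are the method's stated training parameters, not
  tuned values.

A PCA baseline (`pca_compress`, scikit-learn) provides the linear-compression
control at the same bottleneck; for a fully linear autoencoder the PCA
reconstruction error is the provable optimum, which the test suite asserts.

## Search and classification

Retrieval is an exhaustive Euclidean scan (`scipy.spatial.distance.cdist` +
stable argsort). Exact distance ties break by archive insertion order, making
results deterministic and giving the prefix property: enlarging *k* never
drops a previously retrieved hit. Requests with *k* larger than the archive
are clipped (with a flag) and the vote uses the effective hit count. A query
is positive when `m/k ≥ τ`.

## Evaluation

The operating threshold τ is chosen by Youden's index `J = sensitivity +
specificity − 1`, maximised over the ROC of the vote likelihoods. The ROC is
evaluated at every unique score (descending, plus a predict-none sentinel)
under the `≥` rule — on the coarse `m/k` grid, midpoint thresholds induce
exactly the same classifications, so the unique-score grid is used. AUC is
the trapezoidal area, identical to Mann–Whitney concordance with ties
credited ½. Youden ties resolve toward the smaller threshold (higher
sensitivity), the clinically conservative choice for a screening triage tool.

Cross-validation uses ten label-stratified folds (round-robin dealing per
class, so per-class and total fold sizes each differ by at most one;
stratification guarantees positives in every fold at 6% prevalence, which a
plain random split does not at desk scale). Each fold in turn is the
query set against the remaining archive; in encoded mode a fresh compressor
is trained per fold on that fold's archive only, so no query information
leaks into training. The Youden threshold is selected on each fold's own
validation ROC, and per-fold sensitivity/specificity are reported at that
threshold together with the fold AUC.

`wilcoxon_paired` compares two methods' per-fold metrics: two-sided Wilcoxon
signed-rank with zero differences dropped and mid-ranks for ties; the p-value
is exact — a dynamic program over the 2^n sign assignments of the (doubled)
ranks — for n ≤ 25, and a tie-corrected normal approximation above.

## What the synthetic data emulates — and what it does not

**Feature clusters** (`generate_feature_clusters`): two Gaussian classes in
`dim` = 3,072 dimensions whose means differ only within a fixed 256-d
coordinate subspace (difference norm = `separation`, default 6), unit
isotropic noise elsewhere, 6% positive prevalence — the regime in which a
256-d bottleneck can preserve essentially all class signal. The
Bayes-optimal AUC of any score is Φ(separation/√2) ≈ 1 at the default. What
raw high-dimensional kNN voting actually attains is far below this bound:
with 120 positives in an 1,800-item archive, the between-class offset in
squared distance (separation² = 36) is only ≈ 0.26 standard deviations of
the distance noise (√(12·dim)), and an 11-neighbour vote takes only 12
distinct values. The measured tenfold AUCs — raw ≈ 0.78 (k=11) / 0.92
(k=51), encoder codes ≈ 0.91 / 0.97, PCA ≈ 0.73 / 0.94 — therefore
reproduce the method's central qualitative claims: compression *helps*
rather than hurts retrieval, the learned encoder beats the linear baseline,
and the advantage is largest at small k.

**Phantom images** (`generate_phantoms`): negatives are built as functions
of the folded coordinate |x − cx| (bright elliptical lung fields, a
mediastinal band, sinusoidal rib texture, mild per-image jitter applied
before folding), hence *exactly* mirror-symmetric before additive noise;
positives darken a pleural crescent along the lateral lung edge on one
random side (default contrast 0.5, width 12% of the image side — a
conspicuous, not subtle, lesion). Lesion defaults were fixed once at values
giving an unambiguous asymmetry signal well above the noise floor
(σ = 0.01), since the fixture's job is to make the symmetry mechanism
testable, not to calibrate clinical difficulty.

Neither generator models anatomy, acquisition physics, patient positioning,
chest tubes or co-morbid findings, and the stub backbone is not a learned
feature extractor: passing tests demonstrate the correctness and the
statistical behaviour of the pipeline machinery, not clinical performance on
real radiographs.

## Numerical and degenerate-input conventions

* All training/inference in float32; class weights and AUC statistics in
  float64 (float32 accumulation visibly violates the exact weight
  conservation `Σ W_c S_c = S`).
* Single-seed policy: every stochastic component draws from
  `SeedSequence([seed, substream])`; phantom i uses `SeedSequence([seed, i])`,
  so collections are reproducible under reordering.
* Odd image widths split as (floor, ceil); bilinear resizing without
  anti-alias, clipped back to [0, 1]; inputs already at 224 × 224 pass
  through unchanged.
* Empty retrievals, single-class ROC inputs, zero class counts, non-binary
  labels, mismatched dimensions and wrong-phase encoder calls all raise
  `ValueError` with the offending quantity named; a non-finite training loss
  raises with the epoch index.

## Benchmark problem sizes

The shipped benchmark uses a 2,000 × 3,072 store, tenfold CV, k ∈ {11, 51},
encoder widths [3072, 512, 256] with the 10+10-epoch schedule, and 300
phantom images for the image path — sizes chosen so the full suite and the
reproduction script each run in minutes on a single CPU while keeping ≥ 12
positive queries per validation fold.

## Known limitations

* Exhaustive search is O(n·d) per query; fine for desk-scale archives,
  deliberately unoptimised (no approximate index, whose tie behaviour would
  have to be revalidated against the scan).
* The per-fold Youden threshold is chosen on the same fold it is reported
  on, which is mildly optimistic; a nested split would cost positives at 6%
  prevalence and desk scale.
* The exact Wilcoxon enumeration is limited to 25 nonzero differences;
  beyond that the normal approximation is used.
* `StubBackbone` requires the input side to be a multiple of its block size
  (224/32 by default).
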