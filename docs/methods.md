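# Methods

## Problem and model

A tooth-marked tongue shows concave indentations, usually with a local
color change, along the lateral edges where the teeth press. The package
classifies whole photographs (tooth-marked vs. not) from image-level
labels alone, while localizing candidate mark regions weakly, and spends
expert-annotation budget with an active-learning loop.

### Bags of proposals

Every image is covered by an S×S grid of cells (S = image size /
downsampling factor; 64/8 = 8 at the package's test scale). Each cell
contributes one box per anchor, centered on the cell center; anchors are
(w, h) centroids from k-means over box dimensions. Two presets ship:
`published9`, the nine full-resolution clusters (37, 19) … (32, 90) split
across three scales, and `tiny64`, a single shallow scale of three
anchors spanning the synthetic notch diameters on 64-px images. Only the
shallow scale is active by default: tooth marks are small relative to
the image, and a fine grid of small anchors covers them best. No
objectness pre-filtering is applied — without box annotations a
ground-truth-IoU confidence is undefined, so every proposal flows to the
scoring heads and confidence is learned weakly.

### Scoring heads

With R proposals and C = 2 classes:

- detection softmax over regions per class (where?);
- T = 2 classification branches, averaged logits, softmax over classes
  per region (what?);
- image score `y[c] = Σ_r y_cls[r,c] · y_det[c,r]`;
- MIL head `y_mil = softmax_C(x_mil) ⊙ y_cls` and the reweighted score
  `y*[c] = Σ_r y_mil[r,c] · y_det[c,r]` — lowering an instance's MIL
  softmax can only lower its contribution to `y*`, which is what
  suppresses background regions with confidently wrong class scores.

Both image-level losses are negative log-likelihoods of the true class.
Two normalization choices deserve note. First, the printed image-
classification objective is a plain log-likelihood; it is implemented
with the conventional minus sign, as a positive log-probability cannot
be minimized. Second, in the training path both `y` and `y*` are
renormalized to the probability simplex before the log: each class
carries its *own* detection distribution over regions, so the raw
Hadamard sums can approach 1 for both classes simultaneously, and
without renormalization the NLL of the true class never penalizes the
competing class — the argmax decision rule would stay uninformed. The
single-image functional forms in `wsmial.heads` keep the raw
`−log y[y_GT]` contract for `image_loss` and renormalize only inside
`mil_loss`, which is also how the two operations are unit-tested.

### Instance uncertainty and representativeness

The two classification branches are the antagonistic instance
classifiers: their averaged logits make the prediction, their individual
softmaxes disagree where the model is uncertain. Per round, an
*uncertainty* sub-phase (feature extractor frozen) trains the heads on
the supervised loss minus β times the reweighted discrepancy on
unlabeled images — ascending disagreement exactly where the supervised
anchor permits it — and a *representative* sub-phase (classifiers
frozen) trains the feature extractor on the supervised loss plus β times
the discrepancy plus the critic gap, aligning the branches and pulling
unlabeled features toward the labeled pool, while the critic itself
ascends the gap under the parameter clip [−Q, Q].

The per-instance reweight `w_r` is the largest class entry of
`y_mil[r, :]` (configurable: `max`, `true_class`, `l2`). The
MIL-suppressed score is O(1) and near zero for background instances,
which keeps the informativeness scalar on a scale where the printed
pseudo-label threshold δ0 = 0.01 is meaningful; reweighting by the
instance's contribution to the image score (O(1/R)) would make nearly
every image cross the threshold.

Image informativeness: rank instances by `w_r · u_r`
(`u_r = Σ_c |y1 − y2|`), keep the top 2·R_n, keep the R_n of those with
the highest critic score (closest to the labeled distribution), and
average their reweighted discrepancy. Ties break by instance index.

### The loop

Per round: re-fit on D_l ∪ D_pl → evaluate on D_t → return all
pseudo-labels to D_u → adversarial sub-phases (epoch/2 each) → compute
informativeness for every unlabeled image → move the top K to D_l with
their true labels revealed by the expert oracle → pseudo-label remaining
images with informativeness strictly below δ using argmax of the image
score → δ_a = max(0, δ0 − dr·a) → next round, until A rounds or D_u is
exhausted; a closing re-fit then incorporates the last round's labels.
The strict `<` means δ = 0 disables pseudo-labeling. Read literally, the
printed recursive decay δ ← δ − dr·a turns negative by round 4 at the
default settings, so the linear, floored form is used.

Baseline query strategies (random, least-confidence, entropy, k-means
diversity on the image-score vectors) run the same pool mechanics but
train only the supervised detector — no adversarial phases, no
pseudo-labeling — mirroring how classic strategies are compared under a
fixed detection model.

## Test-scale architecture and training

ResNet-scale backbones are out of scope here; the backbone contract is
any map image → R×d features aligned with the grid. At test scale each
proposal is described by pooled pixel statistics computed exactly with
integral images — per-channel means, gray variance, 4×4 gray and
redness (R−G) block means, box-vs-surround contrast, normalized
geometry; 42 dimensions — followed by a trainable ReLU MLP (42→32→32)
and linear heads. Supervised training uses AdamW (lr 5e-3, weight decay
1e-3, minibatch 32) on horizontally flipped-augmented labeled images
(tongues are bilaterally symmetric and marks favor both sides). The
detection logits are divided by a temperature of 0.1 before the softmax
over the 192 proposals: with weight decay keeping logits small, an
untempered softmax stays near uniform and a handful of true notch
instances would be diluted by two orders of magnitude.

Three further numerical choices matter:

- **Cold-started ensemble fits.** The MIL objective is non-convex and
  single fits vary by ±0.1 test accuracy between initializations; warm
  starts carried bad basins across rounds. Each round's supervised model
  is therefore an average (of simplex-normalized scores) over
  `n_restarts` = 2–3 freshly initialized fits, and the closing fit over
  `final_restarts` = 3. All members are kept; nothing is selected on
  test data.
- **Snapshot/restore around the adversarial phases.** Each ensemble
  member carries the uncertainty/representative sub-phases, contributes
  its informativeness, and is then restored to its supervised state, so
  the training trajectory is purely supervised and query strategies
  differ only in which labels they harvest.
- **Scale of the adversarial terms.** The batched discrepancy term is a
  per-region mean (a sum over 192 proposals would dwarf the image-level
  NLLs ~100-fold); β defaults to 0.1, which keeps the ascent phase from
  saturating `u_r` at its maximum of 2 — a saturated discrepancy ranks
  nothing. The critic uses lr 1e-4: with parameters clipped to
  ±Q = 0.01, a head-sized Adam step pins every weight to the clip
  boundary and the representativeness ranking degenerates to noise.

Log arguments are clamped at 1e-8.

## The synthetic cohort

Each 64×64 image: background clutter in muted skin tones with
low-frequency texture and 2–4 blobs; a pinkish ellipse (semi-axes ≈ 17
and 22 px) with a vertical brightness gradient; distractors drawn for
positives and negatives alike — a band of whitish teeth above the
tongue, a darker lip arc around its upper half, a dark crack polyline
(70% of images), and 1–3 ecchymosis-like dark spots inside; Gaussian
pixel noise (σ = 0.02). Positives (Bernoulli with the clinical fraction
401/1108 ≈ 0.36) carry 1–5 notches: circular bites of 6–14 px diameter
carved out of the ellipse boundary (background shows through) with a
2-px darkened halo, positions biased 9:1 to the lateral edges. The
label is positive iff at least one notch was drawn, and every notch's
bounding box is recorded for evaluation only — training never reads
boxes, and the true labels of unlabeled samples live in a vault read
exclusively by the expert-query oracle.

What the generator does *not* emulate: real acquisition optics, specular
highlights, pose and scale variation, inter-annotator disagreement, and
the continuum of mark severity. Passing tests therefore show that the
method's machinery — MIL scoring, uncertainty-driven querying,
pseudo-label gating, weak localization — works as specified on data
with the assumed statistical structure, not that the clinical accuracy
numbers transfer.

## The scaled-down study

`scripts/acceptance.py` and the end-to-end tests run: three seeded
cohorts of 250 images (200 train, 50 test, ~36% positive), 20% of the
training pool labeled initially, A = 5 rounds of K = 20 queries
(i.e. 50% of the pool labeled after round 3, 70% at the end), hybrid
vs. random querying. Reported: mean final test accuracy, mean accuracy
at the 100-label (50%) checkpoint for both strategies, and the fraction
of test positives whose top-scored box overlaps a true notch (IoU > 0).
Problem sizes were chosen so the full study runs in minutes on one CPU.
At these sizes the pseudo-label gate rarely opens (informativeness
stays above δ0 = 0.01 for most of the run); the mechanism is exercised
directly by the bookkeeping tests instead.

## Known limitations

- The expert oracle replays stored ground truth; there is no interactive
  annotation mode and no annotator-noise model.
- With C = 2, the MIL softmax cannot push *both* classes low on a truly
  empty region; background suppression relies on the product with the
  detection distribution.
- Accuracy at 50 test images is quantized in steps of 0.02 and single
  arms of the study have a spread of roughly ±0.05; conclusions are
  drawn from means over seeds.
- Pseudo-labeling at the printed δ0 engages only when the adversarial
  game reaches near-agreement on confident images, which at the test
  scale happens late or not at all; on larger cohorts with longer
  schedules the gate is expected to open earlier.
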