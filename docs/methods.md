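# Methods

## The classification model

A specimen is a set of six view-tagged images, one per standardized
photographic direction (occlusal, apical, buccal, lingual, mesial, distal).
The model treats the set, not the image, as the unit of classification:

1. **Shared-weight view encoder.** Every image is letterboxed to S×S
   (aspect ratio preserved, black padding, content centered; default
   S = 224, the CPU test configurations use 48) and encoded by one
   convolutional network into a d-dimensional feature token. The same
   parameter objects encode all six views — weight sharing is asserted by
   parameter identity in the tests, and encoder parameters are counted once
   regardless of the number of views.
2. **Attention fusion.** The six tokens, plus learned per-view identity
   embeddings (on by default, since the views are semantically distinct
   positions, not an unordered bag) and a learned aggregation token, pass
   through a stack of Transformer encoder blocks (default 2 layers, 8
   heads, feed-forward width 4d). The pooled representation is the
   aggregation token's output (mean pooling over view tokens is the
   alternative, used by the permutation-invariance tests). That pooled
   d-vector is the *set embedding* exported for visualization; a linear
   head on top of it produces the 16 class probabilities.

With view embeddings off and mean pooling, the architecture is permutation
invariant in the views by construction; with view embeddings on it is
equivariant (permuting views together with their embeddings leaves the
output unchanged). Both properties are tested with fixed random weights.

### Encoder choices

* `tiny` (default): four 3×3 conv stages with channel widths d/8, d/4,
  d/2, d, strides 1-2-2-2, ReLU, global average pooling. The first stage
  keeps full resolution so few-pixel cues (cusp pits, thin root stems)
  survive into the strided stages. Small enough that the whole test suite
  trains on one CPU.
* `convnext_s_like`: the ConvNeXt-S stage layout (depths 3/3/27/3, widths
  96/192/384/768) with residual 3×3 blocks standing in for depthwise
  blocks, no pretrained weights. Provided for larger machines; not
  exercised by the CPU tests beyond construction.

### Norm placement (a deliberate deviation)

The fusion blocks are **pre-norm** (`x + attn(LN(x))`), with a LayerNorm on
the incoming view tokens and a final LayerNorm before pooling. The
classical post-norm arrangement is implemented
(`TransformerBlock(pre_norm=False)`) but is not the default: in the short
schedules this package targets (tens of epochs, hundreds of optimizer
steps) post-norm fusion repeatedly failed to leave the uniform-output
saddle — training loss pinned at ln C with identical outputs for every
input — while pre-norm trains reliably. This matches the now-standard
practice for small-data Transformer training.

## Training recipe

| parameter | default | notes |
|---|---|---|
| optimizer | Adam, β₁ = 0.9, β₂ = 0.99 | the two exponential-decay rates |
| weight decay | 0.5, decoupled | applied to weight matrices only, never biases, norm gains, or learned tokens; coupled L2-in-gradient available (`decoupled_decay=False`). 0.5 is unusually large for a decoupled convention; it is the default the recipe specifies, and interacts with the base LR (effective shrink per step = lr·wd) |
| base learning rate | 1e-4 | **not pinned down by the recipe**; 1e-4 is a common choice for attention models at this batch size. The CPU-scale experiments in this repo use 5e-3, which suits the tiny encoder |
| schedule | linear warmup 60 epochs → poly decay, power 1.5 | per-step, reaching exactly 0 at the final step |
| loss | cross-entropy with label smoothing ε = 0.1 | smoothing mass spread over all C classes including the true one |
| batch | 16 specimens = 96 images | one forward pass per specimen set |
| epochs | 300 | CPU tests use 10–20 |
| gradient clipping | global norm 1.0 | stabilizer for short schedules; without it, occasional seeds collapse to uniform output |
| augmentation | rotation/dropout/perspective/affine with p = 0.5/0.2/0.2/0.2 | train-time only; evaluation paths never augment |

Augmentation magnitudes are package choices (rotation ±15°, cutout ≤10% of
area, perspective corner displacement ≤0.2, translation ≤10% with scale
0.9–1.1), all configurable. "Dropout" here is image-level occlusion
(cutout), not layer dropout — it sits among spatial transforms. Draws are
independent per image; intensities are scaled to [0,1] with optional
per-channel standardization.

## Label taxonomy

16 fine classes `U1..U8, L1..L8` (two-digit FDI codes on manifests are
normalized: quadrants 1/2 → U, 3/4 → L; left/right is never represented).
Positions 1–3 are anterior, 4–5 premolar, 6–8 molar; the 6-type level keeps
the jaw (`UA,UP,UM,LA,LP,LM`), the 3-type level drops it (`A,P,M`). The
maps are nested (16→6→3 composes exactly) and exportable as JSON so the
toolkit can carry other label spaces.

**Coarse evaluation semantics.** The default merges *probabilities*: a
super-category's probability is the sum over its members, and all metrics
are computed on the merged matrix. The argmax-then-merge top-1 is reported
alongside (`top1_argmax_merged`). The two differ in one important respect:
argmax-merging can never turn a correct fine prediction into a wrong coarse
one, so its top-1 is provably non-decreasing toward coarser levels — that
is the monotonicity property the test suite asserts. Probability merging
has no such guarantee (a wrong super-category can out-accumulate the true
one even when the fine argmax is correct; e.g. 0.4 on the true anterior
class against 0.3+0.3 split over two premolars), and small inversions do
occur in practice.

Rank convention for top-k: rank(gᵢ) = 1 + #{classes with strictly greater
probability}; ties resolve in favor of the true class and are measure-zero
for real models. Macro sensitivity/specificity divide by the number of
classes (unweighted); classes with zero test support are excluded from the
macro with a warning (a synthetic-only situation). Per-class ROC is a
threshold sweep on the one-vs-rest probability; AUC by the trapezoid rule;
degenerate classes (no positives or no negatives) report AUC as missing
(JSON null). Cohen's κ comes with its asymptotic 95% CI; Fleiss' κ with a
seeded percentile bootstrap over specimens (2,000 resamples by default —
the CI method is a package choice).

## Consensus refinement

Four raters by default: A0 and A1 (weight 2 each — direct observation and
an experienced teacher in the motivating setting) and A2, A3 (weight 1 each
— later image-only re-annotations). Score(category) = summed weight of its
voters; accept the top category iff its score ≥ 4, else remove the
specimen. With total weight 6 and threshold 4 no two categories can reach
the threshold simultaneously (that would need ≥ 8), so no tie-break is ever
exercised under the defaults — the suite enumerates all 16⁴ = 65,536 vote
assignments to confirm both this and the equivalence with the two-condition
restatement. For non-default weight/threshold configurations where two
categories tie at the maximum above threshold, the specimen is removed:
ambiguity filtering is the procedure's purpose, so ties are ambiguity.
Re-annotation rounds are ordinary additional rater columns; the toolkit
attaches no timing semantics to them.

## Synthetic data: what it emulates, and what it does not

The generator fabricates the *information structure* of isolated-tooth
photograph sets, not their appearance. Rendering is 2-D procedural drawing
on a 256×192 canvas (non-square by design, so the letterbox path is always
exercised): top views draw the crown disc with `cusp_count` dark pits
(occlusal anatomy photographs as high-contrast fissures, and a
class-count signal must survive global average pooling); side views draw a
crown block and `root_count` fixed-width root stems — individual roots do
not thin out as the count grows, so root mass scales with count — with
length set by `crown_root_ratio` and tips bent by `jaw_curvature` (sign
encodes the jaw). Evidence is strictly view-local: top views never encode
the root attributes and side views never encode the cusp count (asserted
pixel-exactly in tests). Per-specimen attribute jitter is log-normal;
additive Gaussian pixel noise (σ = 2 intensity levels) is drawn from
counter-derived substreams, so every (specimen, view) render is
bit-reproducible from the seed regardless of generation order.

Two presets:

* `separable_preset` — four zero-jitter classes including a designated
  **view-complementary pair**: C1 is always (3 cusps, 1 root); C2 is
  (3 cusps, 2 roots) or (5 cusps, 1 root) with equal probability. Any top
  view alone confuses half of C2 with C1, any side view the other half —
  exact Bayes accuracy on the pair is 75% from every single view — while
  the six-view joint identifies every class (Bayes 100%). These numbers are
  computed in-package by exhaustive attribute enumeration
  (`bayes_accuracy`) and asserted in tests. A per-class scalar attribute
  set cannot produce such a pair (full-set information is the union of
  per-view information), which is why the class spec carries the optional
  `variants` list.
* `tooth_preset` — sixteen classes shaped like the tooth label space:
  cusp count encodes the position (1–8), root count the position group
  (1/2/3), curvature sign the jaw, with moderate jitter so adjacent
  positions and jaw counterparts are genuinely confusable — the same two
  directions along which the simulated annotators err.

The default annotator panel gives A0/A1 diagonal mass 0.92/0.90 and A2/A3
0.78/0.74, with off-diagonal mass split 60% over adjacent same-jaw
positions and 40% onto the opposite-jaw counterpart.

What passing tests on this generator shows: that the pipeline — set fusion,
vote refinement, hierarchical metrics — behaves correctly and that the
architecture can exploit cross-view evidence no single view carries. What
it does not show: robustness to photographic nuisance (lighting,
background, pose, occlusion, texture), to class imbalance, or to the far
subtler morphological variation of real teeth. Accuracies obtained here do
not transfer to real specimen collections.

## Numerical and engineering choices

* The network stack is NumPy throughout, under a small tape-based
  reverse-mode autodiff engine written for this package (float32;
  convolution by im2col with col2im scatter-add backward; broadcasting
  handled by sum-to-shape). Every primitive is verified against central
  finite differences; training is bit-deterministic given the seed on a
  fixed BLAS configuration.
* Letterboxing splits an odd leftover pixel toward the trailing edge;
  padding intensity is 0. `resize_pad` is idempotent on conforming images.
* Initialization: He-normal for conv kernels, Xavier-uniform for linear
  maps, N(0, 0.02) for tokens and view embeddings; biases and norm shifts
  start at zero.
* Checkpoints are `.npz` archives holding every parameter plus the full
  estimator configuration and class list; loading reconstructs the
  estimator and reproduces predictions to float32 round-off.
* Degenerate inputs fail loudly: zero-area images, non-distribution
  confusion rows, incomplete vote sets, manifests with missing or duplicate
  view tags, non-finite logits.

## Problem sizes used by the CPU experiments

The test suite and `scripts/acceptance.py` size their experiments for a
single CPU: renders at 96×72 letterboxed to 48, embedding dimension 64 with
4 heads and 2 fusion layers, batches of 8 specimens, learning rate 5e-3
with weight decay 0.05. The learning-capability experiment uses the
separable preset with 200 training and 80 test specimens (10 epochs in the
test, 20 in the acceptance script, which averages three model seeds); the
refinement and agreement experiments use a 200-specimen simulated raw test
set; the hierarchical evaluation trains on the 16-class preset with 15
specimens per class (184 train / 56 test at the 0.765 split) for 20 epochs.
These sizes are the package's own desk-scale defaults; nothing in the
method depends on them.

## Known limitations

* The renderer's realism floor is intentional; it cannot support claims
  about photographic robustness (see above).
* The `convnext_s_like` encoder shares only the stage layout with its
  namesake (no depthwise convolutions, layer scale, or pretrained
  weights).
* Fleiss' κ bootstrap CIs are percentile intervals; no bias correction.
* Training on the pure-NumPy engine is practical at desk scale only; the
  full 224-pixel, d = 512, 300-epoch configuration is defined and
  consistent but assumes more compute than the test environment.
* With non-default consensus weights the removed-on-tie rule is a
  convention, not a consequence of the scoring model.
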