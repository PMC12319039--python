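# Methods

`podmatch` implements a two-stage procedure for counting seed-classified
soybean pods on intact (non-disassembled) plants photographed from two
sides.  Stage one is object detection, which this package deliberately does
not re-train: it ingests detection files (or derives oracle detections from
synthetic ground truth).  Stage two — the package's core — compares every
frontal pod crop with every rear pod crop through a shared-weight (Siamese)
similarity network and deduplicates the two views by greedy threshold
matching, so a pod seen from both sides counts once and a pod occluded in
one view is still counted from the other.

## Two-view geometry

The rear photograph is taken after physically rotating the plant 180°, so
its pixel grid is a horizontal mirror of the front view.  `mirror_flip`
realigns the rear image and `flip_boxes` maps rear boxes with
`x'_min = W − x_max`.  ("Mirrored" could in principle mean a vertical or
double reflection; a plant flipped about its long axis on a table produces
a horizontal mirror, which is what we implement, and the synthetic
generator renders rear views in exactly that geometry so the convention is
self-consistent and testable.)  Boxes use a 0-based half-open pixel
convention throughout, `[x_min, x_max) × [y_min, y_max)`, which makes
areas, intersections, and the reflection arithmetic integer-exact on
synthetic scenes.

## Similarity model

Both 105×105 crops (the published input size) pass through one embedding
network — true weight sharing, not two copies — and the verification head
is a logistic classifier on the element-wise absolute difference of the two
embeddings.  This choice is deliberate: `|e₁ − e₂|` makes the score exactly
symmetric, which the matching stage implicitly assumes, and a probability
output is consistent with the 0.5 matching threshold.  Training minimizes
binary cross-entropy of the score against the same-class pair label.
Defaults follow the published operating point: dropout 0.2 (placed between
the two head layers), batch size 32, Adam with learning rate 1e-3.

The `se_resnet50` backbone is the standard 50-layer bottleneck network
(7×7/64 stride-2 stem, max pool, 3/4/6/3 bottlenecks of widths
64/128/256/512, expansion 4) with a squeeze-and-excitation gate inside
every residual unit: global average pool per channel, bottleneck MLP
C → C/r → C (r = 16, the standard reduction) with ReLU then logistic, and
the resulting gates rescale the residual-branch output *before* the skip
addition.  Pinning every gate to 1 reduces the network numerically to plain
`resnet50`, a property the tests exercise at zero tolerance.  The trunk
ends with global average pooling and two fully connected layers producing a
fixed-length embedding (256 for the full nets; any fixed length satisfies
the interface).

The layers (im2col convolution as one GEMM per layer, batch normalization,
max pooling, SE gating, linear/dropout heads) are implemented directly on
numpy with hand-written backward passes, validated against central finite
differences and an independent loop-based re-implementation of the SE
block.  Pre-trained transfer weights are not used anywhere: all training in
the tests starts from seeded He initialization, so every result is
reproducible offline.

### Desk-scale training configuration

Training the 50-layer network for 200 epochs is a GPU-scale exercise; the
package's self-contained experiments instead use `se_resnet_tiny`, a
reduced-depth analog (3×3/16 stem, three SE-bottlenecks of output widths
64/128/128, embedding 64) that keeps every structural ingredient.  The
standard experiment trains on 1,200 pairs sampled from ~700 crops (10
scenes, both views) for 8 epochs — a few minutes on one CPU — and evaluates
on 300 pairs from scenes generated with disjoint seeds.  Held-out pair
accuracy lands near 0.87 with a diagonally dominant prototype confusion
matrix; two- vs three-seed confusions dominate the residual errors, the
same adjacency structure reported for the full-scale system.

## Matching and counting

Given the frontal set f and the mirror-aligned rear set p, frontal
detections are visited in confidence-descending order (ties by index; the
iteration order of the published loop is unstated, so it is fixed and
configurable).  Each visited pod takes the argmax over the not-yet-claimed
rear pods; if that similarity is strictly greater than the threshold
(default 0.5; "greater than" is the published wording, so equality does not
match) the two are declared the same pod and removed, otherwise the frontal
pod is recorded as front-only.  Rear pods never claimed are counted as
rear-only — this is what makes single-view occlusion recoverable; argmax
ties break to the lowest rear index.  Counting: each matched pair
contributes one pod (on a cross-view class disagreement the
higher-confidence detection wins, frontal on ties; configurable to
always-frontal), each survivor contributes one pod of its own class.
Consequences verified as properties: |pairs| + |front_only| = |f| and
|pairs| + |rear_only| = |p| always; max(|f|,|p|) ≤ total ≤ |f|+|p|; the
total is monotone in the threshold; and with an identity-oracle scorer the
fused count equals the true count whenever every pod is visible in at least
one view.

Optimal assignment (Hungarian) is deliberately not used: the published
procedure is sequential and greedy, and the package reproduces exactly that
including its order dependence.

## Synthetic scenes

A scene scatters n ∈ [10, 40] pods on a 640×480 white canvas (the
acquisition background is a white light-absorbing cloth).  A pod of class
k ∈ {1..4} is k tangent ellipses (semi-axes a, 0.8a; a ∈ [8, 13] px) along
a random axis, so class ↔ lobe count and box length grows with class.  The
class mix (0.103/0.330/0.467/0.099) mirrors the strong two-/three-seed
dominance observed in the field data, letting tests probe imbalance
effects.  Occlusion: each pod is independently hidden with probability
`occlusion_rate` in exactly one view (fair coin), so every pod remains
countable from at least one side — the single-side-missed scenario the
correction stage exists for.  No field estimate of the occlusion frequency
is available, so the default rate is 0.2 and the experiments sweep
{0, 0.2, 0.4}.  Per-view appearance jitter (radius ±7%, angle ±6°, color
±18/255) makes two views of the same pod similar but not identical, which
is what makes the similarity task non-trivial.  Everything derives from one
seed; identical configurations render byte-identical images.

What the generator does *not* emulate: stems and branch topology, physical
pod-on-pod overlap (occlusion is a label, not a rendered overlap),
photographic lighting/texture, and five/six-seed mutant pods.  Passing
tests therefore demonstrate the correctness of the correction machinery and
the learnability of shape-based similarity, not field-photograph detection
accuracy.

## Evaluation metrics

Detection: pixel-set IoU; a detection is a true positive when it claims an
unclaimed same-class ground truth at IoU ≥ 0.5 (duplicates of one truth are
false positives); precision, recall, F1; AP is the raw rectangular sum
Σₖ Precision(k)·ΔRecall(k) over the confidence-ranked list — no
interpolation, the literal reading of the published formula (VOC-style
interpolation is available behind `interpolated_ap`); mAP is the plain mean
over the four classes.

Counting: MAE, RMSE, and R = 1 − Σ(tᵢ−cᵢ)²/Σ(tᵢ−t̄)².  This R is a
coefficient of determination (it can be negative) even though the source
calls it a correlation coefficient; it is implemented as printed, with an
ordinary Pearson correlation provided separately as `pearson_r`.  Count
accuracy Acc = 1 − |truth−predict|/truth is left unclamped (negative once
predict > 2·truth) and is undefined at truth = 0; the per-plant comparison
table treats a correctly-predicted empty category as Acc = 1 and an
invented pod in an empty category as undefined (NaN, excluded from that
plant's mean).  Acc_mean averages exactly five categories: the four pod
classes plus the total.

## Numerical and design notes

- Seeds: every stochastic stage (scene draw, jitter, noise, pair sampling,
  weight init, dropout, shuffling) consumes a generator derived from the
  caller's seed; reruns are byte-identical.
- The similarity score of a crop with itself is the same constant for all
  crops (head applied to the zero vector), ~0.5 at initialization.
- Degenerate inputs: empty detection files parse to empty pod sets; an
  empty rear set reduces fusion to the front histogram; a 0×0 similarity
  matrix yields an empty match; constant truth vectors make R undefined
  (error in `count_metrics`, NaN in the table report).
- Float32 is the working precision for the network (float64 for gradient
  checks); matching and metrics are float64.
- Problem sizes in the standard experiments (scene counts, 1,200/300 pairs,
  8 epochs, tiny backbone) were chosen so the full suite runs in minutes on
  one CPU while leaving each claim non-trivial; the full-size 50-layer
  builder is exercised forward-only.

## Known limitations

- No real photographs ship with the package; claims about real-world
  accuracy (mAP 83%, correlation ≥ 0.93) are out of reach without the
  original data and are not asserted.
- The learned-similarity experiment uses class as an identity proxy
  (same-class pairs labeled "same"); true instance-level re-identification
  across views is only exercised through the identity oracle.
- Very dense plants where both views miss pods cannot be corrected by this
  scheme; the fused count is then a lower bound.
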