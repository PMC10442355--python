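# Methods

## The screening model

`pniscreen` treats perineural-invasion detection as a *screening* problem,
not a classification problem. The pipeline mimics how a pathologist works:
recognize nerve and tumor as separate entities, then look for places where
they come together. Formally, each slide yields per-class confidence maps
for tumor and nerve (two independent detectors — the classes are not
mutually exclusive heads of one softmax, because each is thresholded and
curve-swept separately). Components of the thresholded maps are paired, each
pair is scored by the exact minimum Euclidean distance between pixel
centers, and the k closest pairs of a case become candidate fields for
review. The final PNI call is always the (simulated) reviewer's, never the
ranking's: the algorithm only decides *what to look at*, which is what makes
high sensitivity compatible with a modest segmenter.

Distances are between pixel centers, not component boundaries; overlapping
components have distance 0, and 8-adjacent pixels have distance 1 or √2.
"Contact" on a raster therefore means distance ≤ 2 px, and that tolerance is
used wherever true abutment must be recognized (encirclement measurement,
the review rule's contact test).

## Decision rule of the simulated reviewer

A candidate is confirmed when its predicted nerve and tumor components each
overlap a true component of their class **and** the true components satisfy
the histologic criterion:

* nerve *outside* the main tumor body: tumor abutting the nerve
  (distance ≤ 2 px) is PNI;
* nerve *inside* the main tumor body: tumor must cover at least 33% of the
  nerve circumference — the encirclement fraction, measured as the share of
  the nerve component's boundary pixels lying within ε = 3 px of tumor.
  Boundary pixels are component pixels 8-adjacent to non-component pixels
  (raster edges count as outside).

"Inside the main tumor body" has no standard operational definition; here it
is: the nerve component's centroid falls inside the filled convex hull of
the tumor component. This is configurable (`ReviewRule`), and the reviewer
consults ground truth — inter-observer variability is out of scope. A
predicted tumor that overlaps only a benign gland fails the
overlap-with-truth test, which is how the pipeline tolerates the classic
benign-glands-misread-as-tumor failure mode: benign glands do not sit next
to nerves, so their false detections never survive review.

## Operating parameters

| parameter | default | meaning |
|---|---|---|
| confidence threshold | 0.5 | pixel is called positive iff confidence ≥ t (ties included, so t = 0 is total) |
| min component area | 10,000 px (both classes) | foci strictly smaller are discarded before pairing |
| connectivity | 8 | component labeling for both classes |
| k presented fields | 40 (20 for tumor-only cases) | per case, pooled over all its slides |
| max pair distance | 100 px | pairs farther apart are never candidates |
| field size | 512 px | presentation crop, centered on the closest pixel pair, clamped to bounds |
| overlap suppression | IoU > 0.5 | greedy, keep-closest dedup of near-identical fields |
| contact distance | 2 px | rasterization tolerance for "abutting" |
| encirclement threshold | 0.33 | minimum encircled fraction for intratumoral nerves |
| encirclement ε | 3 px | boundary-to-tumor distance counting as "covered" |

The size filter is applied to both classes. Whether it should apply to
tumor only is genuinely ambiguous in the source material; both behaviors are
available via per-class `min_area`, and both-classes is the default because
the filter demonstrably suppresses nerve false alarms as well.

## Synthetic data: what it emulates and what it does not

The generator produces seeded, bit-reproducible scenes:

* **nerves** — smoothed random-walk ribbons (length 460–620 px, thickness
  26–36 px at the default 512 px tile) with wavy internal fiber texture;
* **malignant glands** — lobulated clusters (base radius 62–76 px plus
  lobes), nucleus-speckled basophilic rendering;
* **benign glands** — regular pale disks with a dark epithelial rim, placed
  ≥ 50 px from any nerve (scaled down proportionally on small tiles);
* **planted PNI events** — an extra nerve plus tumor realizing a target
  geometry. Contact/encirclement events wrap a 14 px tumor collar around a
  sub-path spanning the target fraction of the nerve and fuse it with a
  gland-cluster body; distance events push a cluster along the local path
  normal until the measured gap matches the target. Every event is
  *verified on the rasterized mask* (distance within ±2 px, encirclement
  within ±0.1) and redrawn otherwise, with a bounded retry budget and an
  explicit `PlacementError` naming the event on exhaustion.

Structure sizes are deliberately large so that every *true* nerve and tumor
component exceeds the 10,000 px focus filter at default settings — on real
slides the filter's job is to remove segmentation debris, not tissue, and
the synthetic scenes preserve that property. Non-event tumor keeps a ≥ 8 px
gap from every nerve, so planted events are the only true contacts; benign
glands never approach nerves. Case slide counts come from truncated normals
with the study's statistics (27 ± 9.4, or 6.1 ± 1.8 for tumor-only cases,
truncated at 1), and a study of n cases at prevalence q contains exactly
round(n·q) positive cases.

Passing tests on this material shows the *pipeline math* is right — exact
distances, correct filtering, correct ranking, correct review logic, correct
statistics — under controlled error modes. It does not show that any
segmenter reaches clinical accuracy on real H&E tissue: the tiles are
procedural, stain variation, tissue folds, real nerve/gland morphology and
scanner artifacts are absent, and the published analytical-performance
curves of the original study are not reproducible without its slides and
trained weights (a non-goal).

## Segmenters

The **oracle-noise segmenter** corrupts ground truth with controlled error
modes and is the workhorse for pipeline studies: per tile and class it drops
`round(miss_rate · n)` of the n true components (chosen uniformly), adds
Poisson(spurious_rate) spurious foci with areas uniform in a configurable
range (placed disjoint from true nerve/tumor tissue but free to overlap
benign glands, mimicking their misclassification), optionally jitters
component boundaries by dilation/erosion, and draws per-component
confidences from clipped normals. `miss_rate` is implemented as a
deterministic fraction rather than an independent per-component coin flip
because it is specified as *the fraction of true components dropped* —
whereas `spurious_rate` is an *expected count*, hence Poisson. With a zero
noise model the output binarizes back to the ground truth exactly at every
threshold in (0, 1].

The **trainable segmenter** is an ilastik-style pixel classifier:
`skimage.feature.multiscale_basic_features` (intensity/edge/texture at
sigmas 1…2^depth) feeding a small scikit-learn MLP with two independent
sigmoid output heads. Benign glands are trained as background — only
explicit tumor and nerve annotations are positive targets. Training
subsamples pixels per tile with foreground oversampling, optionally doubles
the set with one augmentation draw per tile (flips, right-angle rotations,
brightness/hue jitter; geometric transforms applied identically to the
mask), and is deterministic given the config seed. On easy synthetic tiles
a 40-epoch smoke training reaches held-out per-class pixel IoU well above
0.5 at threshold 0.5; confidences are used raw, with no calibration. This
classifier deliberately trades capacity for trainability on one CPU; it is
not on the pipeline-math acceptance path, which runs entirely on the
oracle-noise segmenter.

## Evaluation conventions

The three metrics are each computed in two interpretations, always reported
side by side with the mode recorded: pixel mode (IoU = |P∩G|/|P∪G|,
detection = recall, false alarm = false-discovery fraction) and object mode
(a truth component is detected when ≥ θ = 0.5 of its pixels are predicted;
a predicted component is false when < θ of it lies in truth; IoU has no
object form and is repeated). Sweeps pool raw counts over the image set
before taking ratios, which keeps images with empty classes well-defined;
the empty-denominator conventions are IoU(∅,∅) = 1, detection(no truth) = 1,
false-alarm(no prediction) = 0.

The study comparison uses the pooled two-proportion z-test without
continuity correction (z² equals the Pearson chi-square of the 2×2 table);
it is the test that reproduces the published p = 0.00088 exactly from the
published counts, which is why it was adopted — McNemar's test on the same
counts does not. The rank-sum comparison (exact enumeration for tie-free
samples with n ≤ 12, tie-corrected normal approximation otherwise) is
provided as the repository's tool for per-case quantities such as
first-positive ranks, without any claim about which test the original
analysis used.

## Numerical and design notes

* Distance transforms are exact Euclidean (`scipy.ndimage
  .distance_transform_edt`); per-nerve-component transforms sampled at tumor
  pixels equal the brute-force all-pairs minimum exactly, which the test
  suite asserts with no tolerance.
* Component labels are numbered in raster-scan order of each component's
  first pixel; the size filter relabels survivors consecutively preserving
  that order.
* Ranking ties (equal distance) break by larger combined component area,
  then (slide, row, column), making the presented order invariant to input
  permutation.
* Candidate encirclement is computed only for pairs in rasterized contact
  (≤ 2 px) and reported as 0 otherwise; the review recomputes geometry on
  ground truth, so segmenter jitter cannot flip a confirmation.
* Study runs process one case at a time and drop slides after screening;
  memory stays flat in the study size. RGB rendering is skipped for
  mask-only studies.
* Problem sizes in the shipped tests and the acceptance script — 30-case
  studies at five replicates, 128 px smoke-training tiles, ≤ 48 px oracle
  rasters — were chosen to exercise every pipeline stage at full fidelity
  while keeping a complete run in the minutes range on a single CPU.

## Known limitations

* Procedural tiles are far from real histology; results transfer to the
  pipeline logic, not to clinical accuracy claims.
* The simulated reviewer is deterministic and omniscient within its rule;
  reading time, fatigue and inter-observer disagreement are not modeled.
* No physical units: areas and distances are in raw pixels, magnification
  is not modeled.
* Whole-slide pyramidal formats are not supported; "slides" are
  single-resolution PNG/TIFF tiles.
* The intratumoral branch of the review rule depends on the convex-hull
  operationalization of "inside the tumor body"; concave tumor masses can
  be judged differently than a pathologist would.
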