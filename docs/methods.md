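# Methods

This note describes the grading pipeline implemented by `gleasongrade`, the
parameter choices and their rationale, the synthetic data generator used for
validation, and the numerical conventions adopted.

## 1. Data model

A slide is an RGB image (`SlideImage`) with a microns-per-pixel value
(default 0.5 μm/px) stored in a JSON sidecar next to the PNG/TIFF pixels.
Annotations (`AnnotationSet`) are polygons in GeoJSON, each carrying a
tissue class and a biopsy identifier; polygons are validated with shapely on
load, and errors name the offending feature index.

Tissue classes form a fixed four-way partition: `STROMA`, `BENIGN_GLAND`,
`GP3` (Gleason pattern 3), and `GP4PLUS` (patterns 4 and 5 merged — the two
are morphologically distinct but their clinical consequence in grade-group
assignment is shared, and merging stabilizes training with few pattern-5
examples). Exclusion polygons override class polygons during rasterization.

Rasterization uses an even-odd (ray-crossing) rule with **boundary pixels
counted inside**, implemented as a vectorized numpy ray-crossing plus
on-segment test. We hand-rolled this rather than using `skimage.draw.polygon`
because we require exact, documented boundary semantics that the library
does not guarantee; a brute-force per-pixel oracle in the test suite pins
the behaviour.

## 2. Patch extraction

Patches are 299×299 px and labelled by the tissue class of their **central
pixel**; eligible centers therefore lie at least 149 px from every slide
border. Patch pixel arrays are numpy views into the slide, so sampling
thousands of patches costs no pixel copies. Per-slide sampling draws
`n_per_class` (default 40) centers uniformly at random per class from the
eligible set, with a warning for classes that have no eligible centers.

Training-time augmentation produces exactly six label-preserving variants —
identity, rotations by 90°/180°/270°, horizontal mirror, vertical mirror —
again as views. Augmentation is applied only to the training side of a fold.

## 3. Biopsy-exclusive balanced partitioning

Cross-validation must never let one biopsy's pixels appear on both sides of
a fold, so partitioning operates on whole biopsies. Each biopsy carries a
per-class patch-count profile; we seek a `k=4`-way split whose per-partition
class counts are as even as possible.

The assignment uses a greedy longest-processing-time pass over biopsies
(sorted by total patch count, seeded shuffle among ties) that places each
biopsy in the partition minimizing the **sum of squared deviations** of
per-(partition, class) counts from their ideal shares, followed by a
deterministic local search (single relocations and pairwise swaps, applied
until a fixpoint) under the same objective. On a 12-biopsy cohort this
matches the exhaustive optimum (verified in the tests by a
meet-in-the-middle enumeration of all 4¹² assignments); we chose the
squared-deviation objective after observing that a plain max-spread greedy
can end far from the optimum.

After partitioning, each (partition, class) cell is subsampled to the
globally smallest cell so every fold trains and evaluates on a perfectly
class-balanced set.

## 4. Patch classifier

The classifier interface (`PatchClassifier`) accepts patches and returns
four-class probabilities. The shipped reference backend is deliberately
lightweight and fully deterministic: per-channel means and standard
deviations, 8-bin channel histograms, and a local-standard-deviation
texture statistic feed a standardized multinomial logistic regression. The
features are invariant under the dihedral augmentation group by
construction, which the tests check. A deep convolutional backend (the
natural production choice at this patch geometry) plugs in through the same
interface; no deep-learning framework is a dependency of this package.

## 5. Probability fusion and maps

Out-of-fold four-class probabilities are fused into three classes —
non-atypical (stroma + benign gland merged), GP3, GP≥4 — by a linear SVM
with Platt calibration (`SVC(kernel="linear", probability=True)`), with the
regularization constant selected from {0.1, 1, 10} by 3-fold grid search on
the out-of-fold table. Fusion learns, rather than hard-codes, how the two
non-atypical probabilities combine. Degenerate (constant) inputs fall back
to a majority-class predictor with a warning; a missing fused class is an
error. Labels are assigned by argmax with lowest-index tie-breaking.

Per-slide probability maps average fused probabilities over a regular grid
of 149-px cells (half the patch side, so neighbouring patches overlap by
half); maps conserve probability mass on defined cells and export as 8-bit
PNGs with a JSON sidecar.

## 6. Slide-level grading

Grid predictions estimate area fractions of GP3 and GP≥4 among atypical
tissue. A pattern is *present* when its fraction is ≥ 4.5% (and > 0); this
threshold suppresses spurious minority patterns caused by isolated
misclassified patches. The majority/minority pair maps to an adjusted grade
group:

| majority | minority | adjusted GG |
|---|---|---|
| GP3  | GP3  | 1 |
| GP3  | GP≥4 | 2 |
| GP≥4 | GP3  | 3 |
| GP≥4 | GP≥4 | 4 |

A single present pattern is doubled (rows 1 and 4); equal fractions grade up
to the GP≥4-majority row; no present pattern yields `BENIGN`, which sits
below grade group 1 on the ordinal scale used for kappa.

## 7. Evaluation

`gleasongrade.metrics` provides confusion matrices, exact concordance
(trace/total), quadratic weighted kappa
(w_ij = 1 − (i−j)²/(k−1)², κ = (p_o − p_e)/(1 − p_e); degenerate margins
raise), and dichotomized sensitivity/specificity/accuracy/F-measure for any
grouping of classes into positive/negative.

**Row-percentage convention.** For matrices stored as row percentages,
dichotomized statistics treat each row's entries as conditional rates with a
**nominal denominator of 100**, combined with class prior weights (uniform
by default, matching balanced evaluation sets). This is not identical to
renormalizing each rounded row — with rounded percentages the two differ,
and the nominal-100 reading is the one under which the shipped benchmark
matrix reproduces its published headline statistics exactly (malignant
sensitivity 90%, specificity 93%, F 0.93; GP≥4 sensitivity 77%). The
equivalence of the two conventions on exact count matrices is tested.

## 8. Synthetic cohort generator

Real slides cannot be distributed, so validation uses seeded
pseudo-histology: each slide is a horizontal tissue band with vertical
class strips whose widths follow the requested composition via
largest-remainder apportionment, rendered in an H&E-like palette with
class-specific gaussian-blob texture and per-pixel noise. Strip rectangles
use inclusive pixel-corner polygons so rasterized areas match the strip
widths exactly. A `texture_separation` dial scales how far apart the class
textures are (1.0 = fully separable, the default study condition).

The default 12-biopsy cohort cycles through compositions spanning benign
slides and adjusted grade groups 1–4, including a biopsy with a 3% GP≥4
strip that exercises the 4.5% presence threshold. Ground-truth grades are
computed from the **rasterized** area fractions by the same grading rule
used at inference — closing the loop between generator, annotation
semantics, and grader.

Limitations: the synthetic textures are far easier than real histology, so
the high recalls and perfect slide-level agreement on synthetic cohorts
validate the pipeline's plumbing and the grading rule, not real-world
classifier performance; the reference feature+linear backend would not
transfer to scanned tissue.

## 9. Problem sizes and defaults

Defaults (12 biopsies, 40 patches per class per slide, 4 folds, 100-px
inference grid stride, 640×2000-px slides) were chosen so a full end-to-end
fit runs in ~2.5 minutes on a single CPU within 8 GiB, while still spanning
all grade groups and every code path (threshold rule, benign extension,
doubling, fold exclusivity). All randomness flows from a single seed through
salted `numpy.random.SeedSequence` spawns, so every stage is independently
reproducible.
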