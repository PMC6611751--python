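# gleasongrade

Automated Gleason grading of prostate biopsy whole-slide images: patch-based
tissue classification, probability fusion, and slide-level assignment of
*adjusted grade groups*.

## Scientific problem

Prostate cancer severity is reported with the Gleason system: a pathologist
identifies the growth patterns present in a biopsy and combines the majority
and minority malignant patterns into a grade group. Manual grading is
time-consuming and shows substantial inter-observer variability, which makes
it a natural target for automated image analysis.

This package implements a complete grading pipeline:

1. **Patch classification.** Square patches (299×299 px at 0.5 μm/px) are cut
   from annotated slides and labelled by the tissue class of their central
   pixel — stroma, benign gland, Gleason pattern 3 (GP3), or Gleason
   pattern ≥ 4 (GP≥4, patterns 4 and 5 merged). A classifier estimates
   four-class probabilities per patch. Training uses six-fold dihedral
   augmentation (identity, three rotations, two mirrors).
2. **Cross-validation.** Biopsies are split into four *biopsy-exclusive*
   partitions balanced per class, so no biopsy ever contributes patches to
   both the training and the evaluation side of a fold.
3. **Probability fusion.** The four class probabilities are fused into three
   clinically relevant ones — non-atypical (stroma + benign gland), GP3, and
   GP≥4 — by a linear support-vector machine with Platt calibration, trained
   on the out-of-fold probabilities.
4. **Slide grading.** Fused labels on a regular grid estimate the area
   fraction of each malignant pattern per biopsy. A pattern counts as
   *present* when its fraction is at least 4.5% of atypical tissue. The
   majority/minority pattern pair maps to an adjusted grade group
   (GP3+GP3 → 1, GP3+GP≥4 → 2, GP≥4+GP3 → 3, GP≥4+GP≥4 → 4; a single
   present pattern is doubled; no present pattern → benign).
5. **Evaluation.** Per-class recall, confusion matrices, exact concordance,
   quadratic weighted kappa, and dichotomized sensitivity/specificity/F-measure
   (including for row-percentage matrices with nominal-100 denominators).

Because real scanned biopsies cannot be bundled, the package ships a seeded
**synthetic pseudo-histology generator** whose slides have known
tissue-class composition, giving an exact ground truth for end-to-end tests.

## Worked example

Grade a synthetic 12-biopsy cohort end to end:

```python
from gleasongrade import CohortSpec, GleasonGradingModel

spec = CohortSpec(n_biopsies=12, seed=1)
model = GleasonGradingModel.from_cohort_spec(spec)
results = model.fit(seed=1)
print(results.summary())
```

Output (verbatim; the fit takes ~2.5 minutes on one CPU):

```
Whole-slide Gleason grading — fit summary
=============================================
slides: 12   biopsies: 12   folds: 4   seed: 1
classifier: feature+multinomial-logistic

Cross-validated patch recall (4 classes):
  stroma          1.000
  benign_gland    0.994
  gp3             0.969
  gp4plus         1.000

Per-biopsy adjusted grade groups:
biopsy_id  frac_gp3  frac_gp4plus majority minority adjusted_gg
biopsy_00  0.500000      0.000000      GP3      GP3           1
biopsy_01  0.500000      0.111111      GP3  GP4PLUS           2
biopsy_02  0.000000      0.000000     None     None      BENIGN
biopsy_03  0.166667      0.444444  GP4PLUS      GP3           3
biopsy_04  0.000000      0.486111  GP4PLUS  GP4PLUS           4
biopsy_05  0.500000      0.000000      GP3      GP3           1
biopsy_06  0.444444      0.166667      GP3  GP4PLUS           2
biopsy_07  0.222222      0.388889  GP4PLUS      GP3           3
biopsy_08  0.000000      0.000000     None     None      BENIGN
biopsy_09  0.500000      0.000000      GP3      GP3           1
biopsy_10  0.500000      0.111111      GP3  GP4PLUS           2
biopsy_11  0.000000      0.500000  GP4PLUS  GP4PLUS           4

Slide-level concordance: 1.000
Quadratic weighted kappa: 1.000
```

Individual stages are available as plain functions — see
`gleasongrade.datamodel`, `.patches`, `.classify`, `.fusion`, `.grading`,
`.metrics`, and `.synthetic` — and through the `gleasongrade` command-line
tool (`synth`, `sample`, `grade`, `evaluate` subcommands).

Grading alone, from known area fractions:

```python
from gleasongrade.grading import assign_adjusted_gg
assign_adjusted_gg(frac_gp3=0.30, frac_gp4plus=0.10).adjusted_gg  # -> 2
assign_adjusted_gg(frac_gp3=0.50, frac_gp4plus=0.02).adjusted_gg  # -> 1 (GP>=4 below 4.5%)
```

## Benchmark matrices

`gleasongrade/data/` ships two reference confusion matrices used as
evaluation benchmarks: a patch-level row-percentage matrix
(non-atypical / GP3 / GP≥4) and a 40-biopsy adjusted-grade-group count
matrix. `gleasongrade.metrics` reproduces their headline statistics —
quadratic weighted kappa 0.70, concordance 65%, malignant-vs-non-atypical
sensitivity 90% / specificity 93% / F-measure 0.93, GP≥4 sensitivity 77%.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers I/O round-trips, a brute-force rasterization oracle, an
exhaustive partitioning optimum (meet-in-the-middle enumeration), a
definitional double-sum kappa oracle, grading worked examples with a
property-based threshold-monotonicity check, and a full end-to-end run on
the synthetic cohort (the slow fixture is shared across tests; the whole
suite takes a few minutes).

## Reproduction

All headline quantities can be recomputed from scratch:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This writes the benchmark statistics above plus the end-to-end synthetic
results (per-class patch recall, slide-level kappa and concordance) to the
JSON file. The benchmark numbers are deterministic; the synthetic numbers
depend only on `--seed`.

See `docs/methods.md` for a detailed methods note.
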