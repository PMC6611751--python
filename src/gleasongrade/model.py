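"""Model/Results facade over the whole-slide grading pipeline.

``GleasonGradingModel`` bundles the stages — patch sampling, balanced
biopsy-exclusive partitioning, four-fold cross-validated patch
classification, probability fusion, grid-based inference and adjusted
grade-group assignment — behind a single ``fit()`` that returns a
``GleasonGradingResults`` carrying per-patch probabilities, per-biopsy
grades, agreement statistics against a reference standard, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import (
    PROB_COLUMNS,
    FeatureLinearClassifier,
    PatchClassifier,
    cross_validate,
    per_class_recall,
)
from .datamodel import AnnotationSet, LabelMask, SlideImage, TissueClass, rasterize
from .fusion import (
    FUSED_COLUMNS,
    FusionModel,
    ProbabilityMap,
    build_probability_map,
    fit_fusion,
    fuse_table,
)
from .grading import GradingConfig, gg_to_ordinal, grade_cohort, grades_to_frame
from .metrics import (
    AgreementReport,
    ConfusionMatrix,
    concordance,
    confusion_matrix,
    quadratic_weighted_kappa,
)
from .patches import HALF, Patch, build_partitions, balance_to_smallest_class, grid_centers, sample_patches

GG_ORDINAL_ORDER = ["BENIGN", "1", "2", "3", "4"]


class GleasonGradingModel:
    """End-to-end grading model over an annotated cohort of slides.

    Parameters
    ----------
    slides : sequence of (SlideImage, AnnotationSet)
        The annotated cohort.  Each biopsy must appear on a single slide.
    reference_grades : DataFrame, optional
        Reference standard with columns ``biopsy_id`` and
        ``true_adjusted_gg``; enables agreement statistics in the results.
    n_per_class : int
        Random training patches drawn per class per slide.
    k : int
        Number of biopsy-exclusive partitions (folds).
    grid_stride : int
        Stride in pixels of the regular inference grid used to estimate
        per-biopsy class fractions (a regular grid tracks area fractions).
    classifier_factory : callable(seed) -> PatchClassifier
        Backend builder; defaults to the deterministic feature+linear
        reference classifier.
    """

    def __init__(
        self,
        slides: Sequence[tuple[SlideImage, AnnotationSet]],
        reference_grades: pd.DataFrame | None = None,
        *,
        n_per_class: int = 40,
        k: int = 4,
        grid_stride: int = 100,
        grading_config: GradingConfig | None = None,
        classifier_factory: Callable[[int], PatchClassifier] | None = None,
        augment: bool = True,
    ) -> None:
        self.slides = list(slides)
        self.reference_grades = reference_grades
        self.n_per_class = n_per_class
        self.k = k
        self.grid_stride = grid_stride
        self.grading_config = grading_config or GradingConfig()
        self.classifier_factory = classifier_factory or (
            lambda seed: FeatureLinearClassifier(seed=seed)
        )
        self.augment = augment

    @classmethod
    def from_cohort_spec(cls, spec, **kwargs) -> "GleasonGradingModel":
        """Build the model from a synthetic CohortSpec (generates the cohort)."""
        from .synthetic import generate_cohort

        slides, truth = generate_cohort(spec)
        return cls(slides, reference_grades=truth, **kwargs)

    def fit(self, seed: int = 0) -> "GleasonGradingResults":
        masks = [rasterize(ann, s.height, s.width) for s, ann in self.slides]
        patches: list[Patch] = []
        for i, ((slide, ann), mask) in enumerate(zip(self.slides, masks)):
            patches.extend(sample_patches(slide, mask, ann, self.n_per_class, seed=seed + i))
        partitions = build_partitions(patches, k=self.k, seed=seed)
        balanced = balance_to_smallest_class(partitions, seed=seed)
        cv_table, fold_models = cross_validate(
            balanced, self.classifier_factory, seed=seed, augment=self.augment, return_models=True
        )
        fusion = fit_fusion(cv_table, seed=seed)

        # area-representative inference on a regular grid, each biopsy
        # predicted by the fold model that never trained on it
        grid_rows = []
        for (slide, ann), mask in zip(self.slides, masks):
            grid_rows.extend(
                self._predict_grid(slide, ann, mask, balanced.assignment, fold_models)
            )
        grid_table = fuse_table(fusion, pd.DataFrame(grid_rows))
        grades = grade_cohort(grid_table, self.grading_config)

        return GleasonGradingResults(
            model=self,
            masks=masks,
            cv_table=cv_table,
            fold_models=fold_models,
            fusion_model=fusion,
            grid_table=grid_table,
            slide_grades=grades_to_frame(grades),
            assignment=dict(balanced.assignment),
            seed=seed,
        )

    def _predict_grid(self, slide, ann, mask, assignment, fold_models):
        from .patches import _center_biopsy_lookup

        centers = grid_centers(mask, self.grid_stride)
        if len(centers) == 0:
            return []
        lookup = _center_biopsy_lookup(ann, mask)
        batch, meta = [], []
        for r, c in centers:
            biopsy = lookup(int(r), int(c))
            if biopsy not in assignment:
                continue  # biopsy contributed no training patches anywhere
            batch.append(
                Patch(
                    pixels=slide.pixels[r - HALF : r + HALF + 1, c - HALF : c + HALF + 1],
                    center=(int(r), int(c)),
                    label=TissueClass(int(mask.grid[r, c])),
                    biopsy_id=biopsy,
                    slide_id=slide.slide_id,
                )
            )
            meta.append((biopsy, assignment[biopsy]))
        rows = []
        for fold in sorted({m[1] for m in meta}):
            idx = [i for i, m in enumerate(meta) if m[1] == fold]
            probs = fold_models[fold].predict_proba([batch[i] for i in idx])
            for j, i in enumerate(idx):
                p = batch[i]
                rows.append(
                    {
                        "patch_id": f"{p.slide_id}:{p.center[0]}:{p.center[1]}",
                        "slide_id": p.slide_id,
                        "biopsy_id": p.biopsy_id,
                        "fold": fold,
                        "center_row": p.center[0],
                        "center_col": p.center[1],
                        **dict(zip(PROB_COLUMNS, probs[j])),
                        "true_label": p.label.name.lower(),
                    }
                )
        return rows


@dataclass
class GleasonGradingResults:
    """Fitted pipeline state, estimates, and agreement diagnostics."""

    model: GleasonGradingModel
    masks: list[LabelMask]
    cv_table: pd.DataFrame
    fold_models: list[PatchClassifier]
    fusion_model: FusionModel
    grid_table: pd.DataFrame
    slide_grades: pd.DataFrame
    assignment: dict[str, int]
    seed: int

    @property
    def patch_recall(self) -> dict[str, float]:
        """Cross-validated four-class recall per tissue class."""
        return per_class_recall(self.cv_table)

    def gg_confusion(self) -> ConfusionMatrix | None:
        """Adjusted-GG confusion matrix against the reference standard."""
        ref = self.model.reference_grades
        if ref is None:
            return None
        merged = self.slide_grades.merge(ref[["biopsy_id", "true_adjusted_gg"]], on="biopsy_id")
        return confusion_matrix(
            [str(gg_to_ordinal(g)) if g != "BENIGN" else "BENIGN" for g in merged["true_adjusted_gg"]],
            [str(gg_to_ordinal(g)) if g != "BENIGN" else "BENIGN" for g in merged["adjusted_gg"]],
            GG_ORDINAL_ORDER,
        )

    @property
    def gg_kappa(self) -> float | None:
        cm = self.gg_confusion()
        return None if cm is None else quadratic_weighted_kappa(cm)

    @property
    def gg_concordance(self) -> float | None:
        cm = self.gg_confusion()
        return None if cm is None else concordance(cm)

    def probability_map(self, slide_id: str, stride: int = 149) -> ProbabilityMap:
        """Fused-probability map of one slide from the grid predictions."""
        sel = self.grid_table[self.grid_table["slide_id"] == slide_id]
        if sel.empty:
            raise ValueError(f"no grid predictions for slide {slide_id!r}")
        slide = next(s for s, _ in self.model.slides if s.slide_id == slide_id)
        centers = sel[["center_row", "center_col"]].to_numpy()
        return build_probability_map(
            slide, centers, sel[FUSED_COLUMNS].to_numpy(), stride_pixels=stride
        )

    def summary(self) -> str:
        lines = [
            "Whole-slide Gleason grading — fit summary",
            "=" * 45,
            f"slides: {len(self.model.slides)}   biopsies: {len(self.assignment)}   "
            f"folds: {self.model.k}   seed: {self.seed}",
            f"classifier: {self.fold_models[0].descriptor}",
            "",
            "Cross-validated patch recall (4 classes):",
        ]
        for name, r in self.patch_recall.items():
            lines.append(f"  {name:<14s} {r:6.3f}")
        lines.append("")
        lines.append("Per-biopsy adjusted grade groups:")
        lines.append(self.slide_grades.to_string(index=False))
        cm = self.gg_confusion()
        if cm is not None:
            lines += [
                "",
                f"Slide-level concordance: {self.gg_concordance:.3f}",
                f"Quadratic weighted kappa: {self.gg_kappa:.3f}",
            ]
        return "\n".join(lines)
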