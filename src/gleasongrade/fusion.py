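"""Probability fusion into three decision classes and probability maps.

The four patch probabilities (stroma, benign gland, GP3, GP>=4) are fused
into three clinically meaningful classes — non-atypical (stroma + benign
glands), GP3, GP>=4 — by a max-margin post-classifier trained on the
cross-validated probability vectors.  Each patch is then assigned the fused
class of highest probability, and per-class probability maps over the slide
are built by averaging fused probabilities of the patch centers falling in
each grid cell.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .classify import PROB_COLUMNS
from .datamodel import SlideImage

FUSED_COLUMNS = ["q_non_atypical", "q_gp3", "q_gp4plus"]


class FusedClass(enum.IntEnum):
    NON_ATYPICAL = 0
    GP3 = 1
    GP4PLUS = 2


#: four-class label name -> fused target
MERGE_MAP = {
    "stroma": FusedClass.NON_ATYPICAL,
    "benign_gland": FusedClass.NON_ATYPICAL,
    "gp3": FusedClass.GP3,
    "gp4plus": FusedClass.GP4PLUS,
}


@dataclass
class FusionModel:
    """Trained max-margin fusion of 4-vectors into calibrated 3-vectors."""

    svm: SVC | None
    classes: np.ndarray  # FusedClass values the SVM was trained on
    fallback_class: int | None = None  # set when the fit was degenerate
    best_C: float | None = None

    def predict_q(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        if p.shape[1] != 4:
            raise ValueError("expected 4-class probability vectors")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("input probability vectors must sum to 1")
        q = np.zeros((len(p), 3))
        if self.fallback_class is not None:
            q[:, self.fallback_class] = 1.0
            return q
        assert self.svm is not None
        raw = self.svm.predict_proba(p)
        q[:, self.classes.astype(int)] = raw
        return q


def fit_fusion(
    table: pd.DataFrame,
    seed: int = 0,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> FusionModel:
    """Fit the fusion classifier on cross-validated class probabilities.

    ``table`` must hold the four probability columns and ``true_label``
    (four-class names); targets are the merged three classes.  A linear
    support-vector machine is selected over a small regularization grid by
    3-fold internal cross-validation, with decision scores turned into
    probabilities by Platt-style pairwise coupling so outputs are valid
    probability vectors.

    Constant (zero-variance) inputs cannot separate anything: the fit
    degenerates to a majority-class predictor with a warning.
    """
    X = table[PROB_COLUMNS].to_numpy(dtype=float)
    y = np.array([int(MERGE_MAP[l]) for l in table["true_label"]])
    present = np.unique(y)
    if len(present) < 3:
        missing = [FusedClass(c).name for c in range(3) if c not in present]
        raise ValueError(f"fusion training data is missing fused classes: {missing}")
    if np.allclose(X.std(axis=0), 0.0):
        majority = int(np.bincount(y).argmax())
        warnings.warn(
            "constant probability vectors: fusion degenerates to the majority class",
            RuntimeWarning,
        )
        return FusionModel(svm=None, classes=present, fallback_class=majority)
    grid = GridSearchCV(
        SVC(kernel="linear", probability=True, random_state=seed),
        {"C": list(c_grid)},
        cv=3,
    )
    grid.fit(X, y)
    svm = grid.best_estimator_
    return FusionModel(svm=svm, classes=svm.classes_, best_C=float(grid.best_params_["C"]))


def fuse(model: FusionModel, p: np.ndarray) -> np.ndarray:
    """Fuse one or many 4-class probability vectors into 3-class vectors."""
    q = model.predict_q(p)
    return q[0] if np.asarray(p).ndim == 1 else q


def assign_label(q: np.ndarray) -> FusedClass:
    """Highest-probability fused class; ties go to the lowest class index."""
    q = np.asarray(q, dtype=float)
    if q.shape != (3,):
        raise ValueError("expected a 3-vector")
    return FusedClass(int(np.argmax(q)))  # np.argmax returns the first maximum


def fuse_table(model: FusionModel, table: pd.DataFrame) -> pd.DataFrame:
    """Append fused probabilities and fused labels to a probability table."""
    q = model.predict_q(table[PROB_COLUMNS].to_numpy(dtype=float))
    out = table.copy()
    for j, col in enumerate(FUSED_COLUMNS):
        out[col] = q[:, j]
    out["fused_label"] = [FusedClass(int(i)).name.lower() for i in q.argmax(axis=1)]
    return out


# ---------------------------------------------------------------------------
# probability maps


@dataclass
class ProbabilityMap:
    """Per-fused-class probability grids over a slide.

    ``grids`` has shape (3, H', W'); ``defined`` marks cells containing at
    least one patch center.  On defined cells the three grids sum to 1.
    """

    grids: np.ndarray
    defined: np.ndarray
    stride_pixels: int
    origin: tuple[int, int] = (0, 0)


def build_probability_map(
    slide: SlideImage,
    centers: np.ndarray,
    fused_probs: np.ndarray,
    stride_pixels: int = 149,
) -> ProbabilityMap:
    """Average fused probabilities of patch centers into a coarse grid.

    Cell (i, j) covers slide pixels [i*stride, (i+1)*stride) x
    [j*stride, (j+1)*stride); its value per class is the mean fused
    probability over all patch centers falling in the cell.  The default
    stride of 149 px (half a patch) keeps neighbouring patches visible in
    adjacent cells.
    """
    if stride_pixels < 1:
        raise ValueError("stride must be >= 1")
    centers = np.asarray(centers, dtype=int)
    fused_probs = np.atleast_2d(np.asarray(fused_probs, dtype=float))
    if len(centers) != len(fused_probs):
        raise ValueError("one probability vector per center is required")
    if len(centers) and (
        centers[:, 0].max() >= slide.height or centers[:, 1].max() >= slide.width
    ):
        raise ValueError("patch centers must lie within the slide")
    hp = -(-slide.height // stride_pixels)
    wp = -(-slide.width // stride_pixels)
    sums = np.zeros((3, hp, wp))
    n = np.zeros((hp, wp))
    for (r, c), q in zip(centers, fused_probs):
        i, j = r // stride_pixels, c // stride_pixels
        sums[:, i, j] += q
        n[i, j] += 1
    defined = n > 0
    grids = np.zeros_like(sums)
    grids[:, defined] = sums[:, defined] / n[defined]
    return ProbabilityMap(grids=grids, defined=defined, stride_pixels=stride_pixels)


def save_probability_map(pmap: ProbabilityMap, out_dir, prefix: str = "map") -> list[str]:
    """Write one 8-bit PNG per fused class (value = round(255*q)) plus a JSON
    sidecar with the stride, origin and the undefined-cell mask path."""
    import json
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, cls in enumerate(FusedClass):
        img = np.round(255 * pmap.grids[k]).astype(np.uint8)
        path = out_dir / f"{prefix}_{cls.name.lower()}.png"
        Image.fromarray(img, mode="L").save(path)
        written.append(str(path))
    mask_path = out_dir / f"{prefix}_defined.png"
    Image.fromarray((pmap.defined * 255).astype(np.uint8), mode="L").save(mask_path)
    sidecar = {
        "stride_pixels": pmap.stride_pixels,
        "origin": list(pmap.origin),
        "defined_mask": str(mask_path),
        "class_images": written,
    }
    (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))
    return written
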