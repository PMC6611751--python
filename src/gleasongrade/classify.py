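"""Pluggable four-class patch classifier and the four-fold cross-validation driver.

The production-scale network behind this pipeline (a deep CNN trained for
days on GPU) is deliberately out of scope: any backend satisfying
``PatchClassifier`` can be plugged in.  The shipped reference backend
summarises each patch with colour-histogram and texture statistics and fits
a multinomial logistic model — fully deterministic under a seed and
trainable in seconds on CPU, which is what the test suite and the synthetic
cohort need.  It makes no claim of fidelity to any particular deep
architecture.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .datamodel import TissueClass
from .patches import Patch, PartitionSet, augment_patch

PROB_COLUMNS = ["p_stroma", "p_benign_gland", "p_gp3", "p_gp4plus"]


class PatchClassifier(abc.ABC):
    """Contract for a four-class patch classifier.

    ``fit`` must be reproducible under the seed it was constructed with and
    ``predict_proba`` deterministic given the trained state; probabilities
    are indexed by TissueClass order and sum to 1.
    """

    descriptor: str = "abstract"

    @abc.abstractmethod
    def fit(self, patches: Sequence[Patch]) -> "PatchClassifier":
        ...

    @abc.abstractmethod
    def predict_proba(self, patches: Sequence[Patch]) -> np.ndarray:
        """(N, 4) array of class probabilities in TissueClass order."""


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Summary features of one RGB patch: per-channel means/stds, 8-bin
    channel histograms, and local-contrast texture statistics.

    All features are invariant to the dihedral augmentations (histograms and
    isotropic local statistics), so the reference backend behaves identically
    on a patch and its rotations.
    """
    px = pixels.astype(np.float32)
    feats = [px.mean(axis=(0, 1)) / 255.0, px.std(axis=(0, 1)) / 255.0]
    for ch in range(3):
        hist = np.bincount((pixels[:, :, ch] >> 5).ravel(), minlength=8).astype(np.float32)
        feats.append(hist / hist.sum())
    gray = px.mean(axis=2)
    local_mean = ndimage.uniform_filter(gray, size=9)
    local_sq = ndimage.uniform_filter(gray * gray, size=9)
    local_std = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
    feats.append(
        np.array(
            [
                local_std.mean() / 255.0,
                local_std.std() / 255.0,
                np.percentile(local_std, 90) / 255.0,
            ],
            dtype=np.float32,
        )
    )
    return np.concatenate(feats)


@dataclass
class FeatureLinearClassifier(PatchClassifier):
    """Reference backend: patch summary features + multinomial logistic model."""

    seed: int = 0
    C: float = 1.0
    max_iter: int = 500
    descriptor: str = "feature+multinomial-logistic"
    _scaler: StandardScaler | None = field(default=None, repr=False)
    _model: LogisticRegression | None = field(default=None, repr=False)
    _classes: np.ndarray | None = field(default=None, repr=False)

    def fit(self, patches: Sequence[Patch]) -> "FeatureLinearClassifier":
        y = np.array([int(p.label) for p in patches])
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least 2 classes")
        X = np.stack([patch_features(p.pixels) for p in patches])
        self._scaler = StandardScaler().fit(X)
        self._model = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.seed
        ).fit(self._scaler.transform(X), y)
        self._classes = self._model.classes_
        return self

    def predict_proba(self, patches: Sequence[Patch]) -> np.ndarray:
        if self._model is None or self._scaler is None or self._classes is None:
            raise RuntimeError("classifier is not fitted")
        X = self._scaler.transform(np.stack([patch_features(p.pixels) for p in patches]))
        raw = self._model.predict_proba(X)
        # expand to all four classes even if some were absent from training
        out = np.zeros((len(patches), len(TissueClass)))
        out[:, self._classes] = raw
        return out


class OracleClassifier(PatchClassifier):
    """Reads the true label off each patch; a testing upper bound, not a model."""

    descriptor = "oracle"

    def fit(self, patches: Sequence[Patch]) -> "OracleClassifier":
        return self

    def predict_proba(self, patches: Sequence[Patch]) -> np.ndarray:
        out = np.zeros((len(patches), len(TissueClass)))
        out[np.arange(len(patches)), [int(p.label) for p in patches]] = 1.0
        return out


def cross_validate(
    ps: PartitionSet,
    factory: Callable[[int], PatchClassifier],
    seed: int = 0,
    augment: bool = True,
    return_models: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[PatchClassifier]]:
    """Four-fold (generally k-fold) cross-validation over the partitions.

    For each fold f the classifier trains on the other partitions (with the
    six-way dihedral augmentation applied to training patches only) and
    predicts the held-out partition un-augmented.  Every output row comes
    from a model that never saw that row's biopsy, which the function
    asserts explicitly.

    Returns a DataFrame with one row per held-out patch: patch_id, slide_id,
    biopsy_id, fold, the four class probabilities, and true_label.
    """
    if any(len(p) == 0 for p in ps.partitions):
        raise ValueError("all partitions must be non-empty")
    rows = []
    models: list[PatchClassifier] = []
    for fold in range(ps.k):
        train: list[Patch] = []
        for p in range(ps.k):
            if p == fold:
                continue
            for patch in ps.partitions[p]:
                train.extend(augment_patch(patch) if augment else [patch])
        train_biopsies = {p.biopsy_id for p in train}
        clf = factory(seed + fold).fit(train)
        models.append(clf)
        test = ps.partitions[fold]
        for patch in test:  # leakage check
            assert patch.biopsy_id not in train_biopsies, (
                f"biopsy {patch.biopsy_id} leaked into fold {fold} training set"
            )
        probs = clf.predict_proba(test)
        for i, patch in enumerate(test):
            rows.append(
                {
                    "patch_id": f"{patch.slide_id}:{patch.center[0]}:{patch.center[1]}:{i}",
                    "slide_id": patch.slide_id,
                    "biopsy_id": patch.biopsy_id,
                    "fold": fold,
                    **dict(zip(PROB_COLUMNS, probs[i])),
                    "true_label": patch.label.name.lower(),
                }
            )
    table = pd.DataFrame(rows)
    return (table, models) if return_models else table


def per_class_recall(table: pd.DataFrame) -> dict[str, float]:
    """Recall of the four-class argmax per true class, from a CV table."""
    probs = table[PROB_COLUMNS].to_numpy()
    pred = probs.argmax(axis=1)
    out = {}
    for tissue in TissueClass:
        sel = table["true_label"] == tissue.name.lower()
        if sel.any():
            out[tissue.name.lower()] = float((pred[sel.to_numpy()] == int(tissue)).mean())
    return out
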