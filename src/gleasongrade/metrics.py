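"""Agreement statistics: confusion matrices, dichotomized metrics,
concordance, and quadratic weighted kappa.

Grade groups are ordinal, so chance-corrected agreement uses the quadratic
weighted kappa: confusing adjusted GG 1 with GG 4 is penalised more than
confusing GG 1 with GG 2.  Patch-level results are summarised by
dichotomizing the three decision classes, e.g. non-atypical versus
malignant (GP >= 3), or GP <= 3 versus GP >= 4.

Published confusion matrices are often printed as row percentages with
rounded cells.  ``dichotomize_metrics`` therefore accepts either raw counts
or a row-percentage matrix; in the latter case each row is treated as a
conditional distribution with a nominal denominator of 100 and combined
with explicit class weights (uniform weights encode balanced test classes),
so rounding noise stays in the cells rather than distorting the margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """k x k agreement table, reference classes on rows, estimates on columns."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} class names"
            )
        if k < 2:
            raise ValueError("need at least 2 classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.class_names)

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class AgreementReport:
    sensitivity: float = math.nan
    specificity: float = math.nan
    accuracy: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f_measure: float = math.nan
    concordance: float = math.nan
    kappa_quadratic: float = math.nan
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "sensitivity",
                "specificity",
                "accuracy",
                "precision",
                "recall",
                "f_measure",
                "concordance",
                "kappa_quadratic",
            )
        }


def confusion_matrix(
    reference: Sequence, estimated: Sequence, class_order: Sequence
) -> ConfusionMatrix:
    """Tally a confusion matrix; labels outside ``class_order`` are an error."""
    if len(reference) != len(estimated):
        raise ValueError("reference and estimated must have equal length")
    names = [str(c) for c in class_order]
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(names), len(names)))
    for r, e in zip(reference, estimated):
        if r not in index or e not in index:
            raise ValueError(f"label {r if r not in index else e!r} not in class_order")
        counts[index[r], index[e]] += 1
    return ConfusionMatrix(counts=counts, class_names=names)


def dichotomize_metrics(
    cm: ConfusionMatrix,
    positive_classes: Sequence,
    class_weights: Sequence[float] | None = None,
    row_percent: bool = False,
) -> AgreementReport:
    """Collapse a k-class matrix to positive-vs-negative and score it.

    With ``row_percent=True`` each row is read as percentages of a nominal
    100 and weighted by ``class_weights`` (uniform if omitted); with counts,
    rows weigh themselves by their own totals.  Sensitivity equals recall;
    F-measure is the harmonic mean of precision and recall.  Metrics whose
    denominator is empty are NaN and listed in ``report.undefined``.
    """
    names = cm.class_names
    pos = [names.index(str(c)) for c in positive_classes]
    if not pos or len(pos) >= cm.k:
        raise ValueError("positive_classes must be a non-empty proper subset")
    neg = [i for i in range(cm.k) if i not in pos]

    if row_percent:
        w = np.ones(cm.k) if class_weights is None else np.asarray(class_weights, float)
        if len(w) != cm.k or np.any(w < 0) or w.sum() == 0:
            raise ValueError("class_weights must be k non-negative reals, not all zero")
        prior = w / w.sum()
        cond = cm.counts / 100.0  # nominal denominator; rounding noise stays in cells
    else:
        if class_weights is not None:
            raise ValueError("class_weights only apply to row-percentage matrices")
        row_sums = cm.counts.sum(axis=1)
        total = row_sums.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        prior = row_sums / total
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(row_sums[:, None] > 0, cm.counts / row_sums[:, None], 0.0)

    tp = float(prior[pos] @ cond[np.ix_(pos, pos)].sum(axis=1))
    fp = float(prior[neg] @ cond[np.ix_(neg, pos)].sum(axis=1)) if neg else 0.0
    tn = float(prior[neg] @ cond[np.ix_(neg, neg)].sum(axis=1)) if neg else 0.0
    pos_mass = float(prior[pos].sum())
    neg_mass = float(prior[neg].sum())

    rep = AgreementReport()
    if pos_mass > 0:
        rep.sensitivity = tp / pos_mass
        rep.recall = rep.sensitivity
    else:
        rep.undefined += ["sensitivity", "recall"]
    if neg_mass > 0:
        rep.specificity = tn / neg_mass
    else:
        rep.undefined.append("specificity")
    rep.accuracy = tp + tn
    if tp + fp > 0:
        rep.precision = tp / (tp + fp)
    else:
        rep.undefined.append("precision")
    if not math.isnan(rep.precision) and not math.isnan(rep.recall) and (
        rep.precision + rep.recall
    ) > 0:
        rep.f_measure = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
    else:
        rep.undefined.append("f_measure")
    return rep


def concordance(cm: ConfusionMatrix) -> float:
    """Exact-agreement fraction: trace over total."""
    total = cm.total()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / total


def quadratic_weighted_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected ordinal agreement with quadratic weights.

    Agreement weights are w_ij = 1 - (i - j)^2 / (k - 1)^2 over the ordered
    class indices; kappa = (p_o - p_e) / (1 - p_e) with p_o the weighted
    observed agreement and p_e the weighted agreement expected from the
    margins alone.
    """
    n = cm.total()
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = cm.k
    i, j = np.indices((k, k))
    w = 1.0 - (i - j) ** 2 / (k - 1) ** 2
    obs = cm.counts / n
    expected = np.outer(cm.counts.sum(axis=1), cm.counts.sum(axis=0)) / (n * n)
    p_o = float((w * obs).sum())
    p_e = float((w * expected).sum())
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("degenerate margins: expected agreement is 1, kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# benchmark confusion matrices (published clinical evaluation of this
# grading procedure; shipped so the printed statistics can be recomputed)


def load_benchmark_patch_matrix() -> ConfusionMatrix:
    """3-class patch confusion matrix in row percentages (balanced classes)."""
    return _load_csv_matrix("patch_confusion_rowpct.csv")


def load_benchmark_gg_matrix() -> ConfusionMatrix:
    """4x4 adjusted grade-group confusion matrix (counts, N = 40 biopsies)."""
    return _load_csv_matrix("gg_confusion_counts.csv")


def _load_csv_matrix(name: str) -> ConfusionMatrix:
    with resources.files("gleasongrade.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(counts=df.to_numpy(dtype=float), class_names=list(df.columns))
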