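"""Patch extraction, dihedral augmentation, and balanced biopsy-exclusive partitioning.

Training examples are 299x299 pixel RGB patches (about 150x150 um at
0.5 um/px) whose class is defined by the label of the central pixel.
Patches are drawn at random with replacement, so overlap is allowed.  For
four-fold cross-validation, whole biopsies are assigned to partitions (a
biopsy never spans two partitions, which prevents leakage of nearly
identical tissue between training and test folds), partitions are balanced
greedily on per-class patch counts, and finally every (partition, class)
cell is downsampled to the globally smallest cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .datamodel import EXCLUDED, PATCH_SIZE, AnnotationSet, LabelMask, SlideImage, TissueClass

logger = logging.getLogger(__name__)

HALF = PATCH_SIZE // 2  # 149; a center needs +-149 pixels of slide around it

AUGMENTATION_TAGS = ("identity", "rot90", "rot180", "rot270", "mirror_h", "mirror_v")


@dataclass
class Patch:
    """A 299x299 RGB block labelled by its central pixel."""

    pixels: np.ndarray  # 299 x 299 x 3 uint8 (may be a view into the slide)
    center: tuple[int, int]  # (row, col) in slide coordinates
    label: TissueClass
    biopsy_id: str
    slide_id: str = ""
    augmentation_tag: str = "identity"

    def __post_init__(self) -> None:
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(
                f"patch pixels must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {self.pixels.shape}"
            )
        if self.augmentation_tag not in AUGMENTATION_TAGS:
            raise ValueError(f"unknown augmentation tag {self.augmentation_tag!r}")


@dataclass
class PartitionSet:
    """k biopsy-exclusive lists of patches plus the biopsy -> partition map."""

    partitions: list[list[Patch]]
    assignment: dict[str, int]

    @property
    def k(self) -> int:
        return len(self.partitions)

    def cell_counts(self) -> np.ndarray:
        """k x 4 matrix of patch counts per (partition, class)."""
        counts = np.zeros((self.k, len(TissueClass)), dtype=int)
        for p, patches in enumerate(self.partitions):
            for patch in patches:
                counts[p, int(patch.label)] += 1
        return counts


def _rng(seed: int, salt: int) -> np.random.Generator:
    # one named stream per operation so stages are independently reproducible
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(salt,)))


def eligible_centers(mask: LabelMask, tissue_class: TissueClass) -> np.ndarray:
    """(N, 2) array of (row, col) centers whose class matches and whose full
    299-window lies inside the slide.  EXCLUDED pixels never qualify (the
    mask stores EXCLUDED in place of any class code)."""
    grid = mask.grid
    h, w = grid.shape
    interior = np.zeros_like(grid, dtype=bool)
    if h >= PATCH_SIZE and w >= PATCH_SIZE:
        interior[HALF : h - HALF, HALF : w - HALF] = True
    rows, cols = np.nonzero((grid == int(tissue_class)) & interior)
    return np.column_stack([rows, cols])


def sample_patches(
    slide: SlideImage,
    mask: LabelMask,
    ann: AnnotationSet,
    n_per_class: int,
    seed: int,
) -> list[Patch]:
    """Randomly draw up to ``n_per_class`` patches per tissue class.

    Centers are uniform over eligible pixels, drawn with replacement so
    patches may overlap.  A class with no eligible pixels yields zero
    patches and a warning.  Patch pixel blocks are views into the slide
    array to keep memory proportional to the slide, not the patch count.
    """
    if mask.grid.shape != (slide.height, slide.width):
        raise ValueError("mask dimensions do not match the slide")
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    # map each eligible center to its biopsy via the nearest containing region
    biopsy_of = _center_biopsy_lookup(ann, mask)
    rng = _rng(seed, salt=1)
    patches: list[Patch] = []
    for tissue in TissueClass:
        centers = eligible_centers(mask, tissue)
        if len(centers) == 0:
            if n_per_class > 0:
                logger.warning(
                    "slide %s: no eligible centers for class %s", slide.slide_id, tissue.name
                )
            continue
        idx = rng.integers(0, len(centers), size=n_per_class)
        for r, c in centers[idx]:
            patches.append(
                Patch(
                    pixels=slide.pixels[r - HALF : r + HALF + 1, c - HALF : c + HALF + 1],
                    center=(int(r), int(c)),
                    label=tissue,
                    biopsy_id=biopsy_of(int(r), int(c)),
                    slide_id=slide.slide_id,
                )
            )
    return patches


def _center_biopsy_lookup(ann: AnnotationSet, mask: LabelMask) -> Callable[[int, int], str]:
    """Return a function mapping a labelled pixel to the biopsy_id of the
    annotation region containing it (last matching region wins, mirroring
    rasterization overwrite order)."""
    from .datamodel import points_in_polygon

    def lookup(r: int, c: int) -> str:
        found = ""
        for region in ann.regions:
            if points_in_polygon(np.array([r]), np.array([c]), region.polygon)[0]:
                found = region.biopsy_id
        if not found:
            raise ValueError(f"pixel ({r}, {c}) is labelled but inside no annotation region")
        return found

    return lookup


# ---------------------------------------------------------------------------
# augmentation

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
    "mirror_h": lambda a: a[:, ::-1],  # flip left-right
    "mirror_v": lambda a: a[::-1, :],  # flip up-down
}


def augment_patch(patch: Patch) -> list[Patch]:
    """The six training variants: identity, 90/180/270 rotation, two mirrors.

    Label, center, biopsy and slide identity are shared; only pixels and the
    augmentation tag differ.  Outputs are views (no pixel copies).
    """
    return [
        replace(patch, pixels=f(patch.pixels), augmentation_tag=tag)
        for tag, f in _TRANSFORMS.items()
    ]


# ---------------------------------------------------------------------------
# partitioning and balancing


def build_partitions(patches: Sequence[Patch], k: int = 4, seed: int = 0) -> PartitionSet:
    """Assign whole biopsies to ``k`` partitions, balancing per-class counts.

    Greedy longest-processing-time pass — biopsies sorted by total patch
    count descending (ties shuffled reproducibly by ``seed``), each placed in
    the partition minimizing the squared deviation of per-class cell counts
    from their ideal equal share — followed by a deterministic local search
    (single-biopsy relocations and pairwise swaps to fixpoint) on the same
    objective.  The squared deviation is a smooth surrogate for the
    max-class-spread balance metric; ties always go to the lowest partition
    index so the result is deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_biopsy: dict[str, list[Patch]] = {}
    for p in patches:
        if not p.biopsy_id:
            raise ValueError("every patch needs a biopsy_id")
        by_biopsy.setdefault(p.biopsy_id, []).append(p)
    if len(by_biopsy) < k:
        raise ValueError(
            f"cannot build {k} biopsy-exclusive partitions from {len(by_biopsy)} biopsies"
        )
    profiles = {
        b: np.bincount([int(p.label) for p in ps], minlength=len(TissueClass))
        for b, ps in by_biopsy.items()
    }
    target = sum(profiles.values()) / k  # ideal per-class cell counts

    def objective(counts: np.ndarray) -> float:
        return float(((counts - target) ** 2).sum())

    order = sorted(by_biopsy)
    _rng(seed, salt=2).shuffle(order)
    order.sort(key=lambda b: -int(profiles[b].sum()))  # stable: ties keep shuffled order

    counts = np.zeros((k, len(TissueClass)), dtype=float)
    assignment: dict[str, int] = {}
    for b in order:
        objs = []
        for p in range(k):
            trial = counts.copy()
            trial[p] += profiles[b]
            objs.append(objective(trial))
        best = int(np.argmin(objs))  # lowest index wins ties
        counts[best] += profiles[b]
        assignment[b] = best

    # local search: relocations then swaps, first improvement, to fixpoint
    biopsies = list(order)
    improved = True
    while improved:
        improved = False
        cur = objective(counts)
        for b in biopsies:
            p0 = assignment[b]
            for p in range(k):
                if p == p0:
                    continue
                trial = counts.copy()
                trial[p0] -= profiles[b]
                trial[p] += profiles[b]
                if objective(trial) < cur - 1e-9:
                    counts, assignment[b], cur = trial, p, objective(trial)
                    p0 = p
                    improved = True
        for i, b1 in enumerate(biopsies):
            for b2 in biopsies[i + 1 :]:
                p1, p2 = assignment[b1], assignment[b2]
                if p1 == p2:
                    continue
                trial = counts.copy()
                trial[p1] += profiles[b2] - profiles[b1]
                trial[p2] += profiles[b1] - profiles[b2]
                if objective(trial) < cur - 1e-9:
                    counts = trial
                    assignment[b1], assignment[b2] = p2, p1
                    cur = objective(trial)
                    improved = True

    partitions: list[list[Patch]] = [[] for _ in range(k)]
    for b, ps in by_biopsy.items():
        partitions[assignment[b]].extend(ps)
    return PartitionSet(partitions=partitions, assignment=assignment)


def max_class_spread(counts: np.ndarray) -> int:
    """Balance objective: the largest across-partition spread of any class."""
    counts = np.asarray(counts)
    return int((counts.max(axis=0) - counts.min(axis=0)).max())


def balance_to_smallest_class(ps: PartitionSet, seed: int = 0) -> PartitionSet:
    """Subsample every (partition, class) cell to the global minimum cell count.

    Sampling is without replacement and seeded; the biopsy assignment map is
    unchanged.  Empty cells are an error because the balanced count would be
    zero everywhere.
    """
    counts = ps.cell_counts()
    empty = [
        (p, TissueClass(c).name)
        for p in range(ps.k)
        for c in range(counts.shape[1])
        if counts[p, c] == 0
    ]
    if empty:
        raise ValueError(f"cannot balance: empty (partition, class) cells {empty}")
    target = int(counts.min())
    rng = _rng(seed, salt=3)
    new_partitions: list[list[Patch]] = []
    for patches in ps.partitions:
        kept: list[Patch] = []
        for tissue in TissueClass:
            members = [p for p in patches if p.label == tissue]
            pick = rng.choice(len(members), size=target, replace=False)
            kept.extend(members[i] for i in sorted(pick))
        new_partitions.append(kept)
    return PartitionSet(partitions=new_partitions, assignment=dict(ps.assignment))


def grid_centers(mask: LabelMask, stride: int) -> np.ndarray:
    """Regular grid of eligible (row, col) centers over labelled pixels.

    Used at inference time to estimate per-biopsy class fractions: a regular
    grid samples area evenly, so patch-label fractions track area fractions.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = mask.grid.shape
    rows = np.arange(HALF, h - HALF, stride)
    cols = np.arange(HALF, w - HALF, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    labels = mask.grid[centers[:, 0], centers[:, 1]]
    return centers[labels >= 0]
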