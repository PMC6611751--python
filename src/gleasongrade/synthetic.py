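"""Procedural pseudo-histology: annotated synthetic biopsies for end-to-end tests.

Real graded prostate biopsies cannot ship with a test suite, so this module
draws elongated biopsy-like bands on a white background, partitioned into
contiguous regions of the four tissue classes with areas proportional to a
requested composition.  Each class gets a parametric texture in an
H&E-like palette (pink stroma, progressively darker purple epithelium with
gland-like lumina shrinking from benign glands to pattern >=4), so class
separability is controlled by a single ``texture_separation`` dial: at 1.0
the classes are far apart in colour space and a simple classifier resolves
them; near 0 they collapse into a deliberately hard cohort.

Textures are parametric, not learned; nothing here models real nuclear
morphology, stain variation, or scanner artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .datamodel import (
    AnnotatedRegion,
    AnnotationSet,
    SlideImage,
    TissueClass,
    rasterize,
    save_annotations,
    save_slide,
)
from .grading import GradingConfig, SlideGrade, grade_from_area_fractions

logger = logging.getLogger(__name__)

CLASS_ORDER = (TissueClass.STROMA, TissueClass.BENIGN_GLAND, TissueClass.GP3, TissueClass.GP4PLUS)

# H&E-like base palette (visual plausibility only)
_BASE_COLORS = {
    TissueClass.STROMA: np.array([236.0, 176.0, 198.0]),
    TissueClass.BENIGN_GLAND: np.array([198.0, 152.0, 212.0]),
    TissueClass.GP3: np.array([160.0, 106.0, 178.0]),
    TissueClass.GP4PLUS: np.array([118.0, 68.0, 140.0]),
}
_MEAN_COLOR = np.mean(list(_BASE_COLORS.values()), axis=0)

# blob length scale (gaussian sigma, px) and lumen fraction per class
_TEXTURE = {
    TissueClass.STROMA: (2.0, 0.0),
    TissueClass.BENIGN_GLAND: (12.0, 0.35),
    TissueClass.GP3: (5.0, 0.25),
    TissueClass.GP4PLUS: (3.0, 0.08),
}

DEFAULT_SIZE = (640, 2000)
_MIN_STRIP_WIDTH = 2  # px; narrower regions cannot be annotated meaningfully

Composition = tuple[float, float, float, float]  # stroma, benign, gp3, gp4plus

# A grade-group-1-heavy default mix, the typical skew of a diagnostic biopsy
# cohort: 2 benign, 3 GG1, 3 GG2, 2 GG3, 2 GG4 per 12 biopsies.
DEFAULT_COMPOSITION_CYCLE: tuple[Composition, ...] = (
    (0.25, 0.25, 0.50, 0.00),  # GG1
    (0.20, 0.20, 0.45, 0.15),  # GG2
    (0.50, 0.50, 0.00, 0.00),  # benign
    (0.20, 0.20, 0.15, 0.45),  # GG3
    (0.25, 0.25, 0.00, 0.50),  # GG4
    (0.30, 0.20, 0.47, 0.03),  # GG1 (GP>=4 below the 4.5% presence threshold)
    (0.15, 0.25, 0.40, 0.20),  # GG2
    (0.25, 0.15, 0.20, 0.40),  # GG3
    (0.45, 0.55, 0.00, 0.00),  # benign
    (0.28, 0.22, 0.50, 0.00),  # GG1
    (0.22, 0.18, 0.44, 0.16),  # GG2
    (0.22, 0.28, 0.00, 0.50),  # GG4
)


@dataclass
class CohortSpec:
    n_biopsies: int = 12
    compositions: Sequence[Composition] | None = None
    texture_separation: float = 1.0
    seed: int = 0
    size: tuple[int, int] = DEFAULT_SIZE

    def __post_init__(self) -> None:
        if self.n_biopsies < 1:
            raise ValueError("n_biopsies must be >= 1")
        if not 0.0 < self.texture_separation <= 1.0:
            raise ValueError("texture_separation must be in (0, 1]")
        if self.compositions is None:
            cyc = DEFAULT_COMPOSITION_CYCLE
            self.compositions = [cyc[i % len(cyc)] for i in range(self.n_biopsies)]
        if len(self.compositions) != self.n_biopsies:
            raise ValueError("need one composition per biopsy")
        for comp in self.compositions:
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError(f"composition {comp} does not sum to 1")


def generate_slide(
    composition: Composition,
    size: tuple[int, int] = DEFAULT_SIZE,
    seed: int = 0,
    texture_separation: float = 1.0,
    biopsy_id: str = "biopsy_0",
    slide_id: str = "slide_0",
    margin: int = 20,
) -> tuple[SlideImage, AnnotationSet]:
    """One synthetic biopsy band with matching polygon annotations.

    The band spans the image minus a white margin and is split along its
    long axis into contiguous class strips with widths proportional to the
    composition.  Strips too narrow to annotate are dropped with a warning.
    Fully reproducible under ``seed``.
    """
    h, w = size
    if h < 600 or w < 600:
        raise ValueError("slide must be at least 600x600 so 299-patches fit")
    if abs(sum(composition) - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    pixels = np.full((h, w, 3), 255.0)
    r0, r1 = margin, h - margin  # band rows [r0, r1)
    c0, c1 = margin, w - margin
    widths = _proportional_widths(composition, c1 - c0)
    ann = AnnotationSet()
    col = c0
    for tissue, width in zip(CLASS_ORDER, widths):
        if width == 0:
            col += width
            continue
        if width < _MIN_STRIP_WIDTH:
            logger.warning(
                "biopsy %s: %s region of width %d px is too small, dropped",
                biopsy_id,
                tissue.name,
                width,
            )
            col += width
            continue
        strip = _render_strip(rng, tissue, r1 - r0, width, texture_separation)
        pixels[r0:r1, col : col + width] = strip
        # inclusive pixel-corner polygon: covers centers col..col+width-1
        poly = np.array(
            [
                [col, r0],
                [col + width - 1, r0],
                [col + width - 1, r1 - 1],
                [col, r1 - 1],
            ],
            dtype=float,
        )
        ann.regions.append(AnnotatedRegion(poly, tissue, biopsy_id))
        col += width
    noise = rng.normal(0.0, 5.0, size=pixels.shape)
    img = np.clip(pixels + noise, 0, 255).astype(np.uint8)
    return SlideImage(slide_id=slide_id, pixels=img), ann


def _proportional_widths(composition: Composition, total: int) -> list[int]:
    """Largest-remainder apportionment of band width to class fractions."""
    exact = np.asarray(composition, dtype=float) * total
    base = np.floor(exact).astype(int)
    base[np.asarray(composition) == 0] = 0
    remainder = total - base.sum()
    order = np.argsort(-(exact - base))
    for i in range(remainder):
        base[order[i % len(base)]] += 1
    return [int(b) for b in base]


def _render_strip(
    rng: np.random.Generator,
    tissue: TissueClass,
    height: int,
    width: int,
    separation: float,
) -> np.ndarray:
    base = _MEAN_COLOR + separation * (_BASE_COLORS[tissue] - _MEAN_COLOR)
    sigma, lumen_frac = _TEXTURE[tissue]
    field_ = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma)
    out = np.empty((height, width, 3))
    out[:] = base
    if lumen_frac > 0:
        # top quantile of the smoothed field becomes white gland lumina
        thresh = np.quantile(field_, 1.0 - lumen_frac)
        lumen = field_ >= thresh
        out[lumen] = 0.3 * base + 0.7 * 255.0
    # dark nuclei-dense pockets in the bottom quantile
    dark = field_ <= np.quantile(field_, 0.2)
    out[dark] = base * (1.0 - 0.25 * separation)
    return out


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[tuple[SlideImage, AnnotationSet]], pd.DataFrame]:
    """Generate a cohort of slides plus a ground-truth grade table.

    Ground-truth adjusted grade groups are computed from the *rasterized*
    annotation areas through the same threshold-and-sum grading rule applied
    to predictions, so the generator and the grader close the loop exactly.
    When ``out_dir`` is given, PNG images, GeoJSON annotations and
    ``ground_truth.csv`` are written there.
    """
    slides: list[tuple[SlideImage, AnnotationSet]] = []
    records = []
    cfg = GradingConfig()
    for i, comp in enumerate(spec.compositions):
        slide, ann = generate_slide(
            comp,
            size=spec.size,
            seed=spec.seed + i,
            texture_separation=spec.texture_separation,
            biopsy_id=f"biopsy_{i:02d}",
            slide_id=f"slide_{i:02d}",
        )
        slides.append((slide, ann))
        mask = rasterize(ann, slide.height, slide.width)
        fracs = {c.name.lower(): f for c, f in mask.class_fractions().items()}
        grade = grade_from_area_fractions(fracs, cfg, biopsy_id=f"biopsy_{i:02d}")
        records.append(
            {
                "biopsy_id": grade.biopsy_id,
                "slide_id": slide.slide_id,
                "frac_stroma": fracs["stroma"],
                "frac_benign_gland": fracs["benign_gland"],
                "frac_gp3": fracs["gp3"],
                "frac_gp4plus": fracs["gp4plus"],
                "true_adjusted_gg": grade.adjusted_gg,
            }
        )
    truth = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for slide, ann in slides:
            save_slide(slide, out_dir / f"{slide.slide_id}.png")
            save_annotations(ann, out_dir / f"{slide.slide_id}.geojson")
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return slides, truth
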