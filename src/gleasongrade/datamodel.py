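"""Core domain types and I/O for slides, polygon annotations, and label masks.

The pipeline works on hematoxylin-and-eosin stained prostate biopsy images at
the 0.5 micron/pixel convention of 20x whole-slide scans.  Tissue is annotated
with four classes: unaffected stroma, non-atypical glands (including LGPIN),
Gleason pattern 3, and Gleason pattern >=4 (patterns 4 and 5 merged, since
pattern 5 is too rare to form its own class).  Regions that cannot be graded
(folds, ink, out-of-focus, inconclusive immunohistochemistry) are carried as
exclusion polygons that override any class annotation.

Coordinate convention: 0-based pixel indices, x = column (rightwards),
y = row (downwards).  Polygons are in pixel units.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

PATCH_SIZE = 299
DEFAULT_MICRONS_PER_PIXEL = 0.5

# LabelMask sentinel codes (class codes are the TissueClass values 0..3)
UNLABELED = -1
EXCLUDED = -2


class TissueClass(enum.IntEnum):
    """Four-way tissue label. STROMA and BENIGN_GLAND form the non-atypical pair."""

    STROMA = 0
    BENIGN_GLAND = 1
    GP3 = 2
    GP4PLUS = 3

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "TissueClass":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown tissue class {name!r}; expected one of "
                f"{[m.name.lower() for m in cls]}"
            ) from None


_DISPLAY_NAMES = {
    TissueClass.STROMA: "unaffected stroma",
    TissueClass.BENIGN_GLAND: "non-atypical gland",
    TissueClass.GP3: "Gleason pattern 3",
    TissueClass.GP4PLUS: "Gleason pattern >=4",
}

#: class name accepted in annotation files for exclusion regions
EXCLUDE_NAME = "exclude"


@dataclass
class SlideImage:
    """An RGB slide (or tile) with its physical pixel size."""

    slide_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide {self.slide_id!r}: expected H x W x 3 RGB pixels, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError(
                f"slide {self.slide_id!r}: expected uint8 pixels, got {self.pixels.dtype}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotatedRegion:
    """One labelled polygon belonging to a single biopsy."""

    polygon: np.ndarray  # V x 2 array of (x, y) vertices, pixel units
    tissue_class: TissueClass
    biopsy_id: str

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be a V x 2 array with V >= 3")
        if not self.biopsy_id:
            raise ValueError("region has an empty biopsy_id")


@dataclass
class AnnotationSet:
    """All class regions and exclusion polygons of one slide."""

    regions: list[AnnotatedRegion] = field(default_factory=list)
    exclusions: list[np.ndarray] = field(default_factory=list)

    def biopsy_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.biopsy_id, None)
        return list(seen)


@dataclass
class LabelMask:
    """Per-pixel labels rasterized from an AnnotationSet.

    ``grid`` holds TissueClass values (0..3) plus the sentinels UNLABELED (-1)
    and EXCLUDED (-2).  EXCLUDED always overrides class codes.
    """

    grid: np.ndarray  # H x W int8

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def class_fractions(self) -> dict[TissueClass, float]:
        """Area fraction of each class among labelled (non-excluded) pixels."""
        labelled = self.grid >= 0
        total = int(labelled.sum())
        if total == 0:
            return {c: 0.0 for c in TissueClass}
        return {c: float((self.grid == int(c)).sum()) / total for c in TissueClass}


# ---------------------------------------------------------------------------
# image I/O


def load_slide(path: str | Path, microns_per_pixel: float | None = None) -> SlideImage:
    """Load a TIFF or PNG RGB image as a SlideImage.

    A JSON sidecar ``<path>.meta.json`` may supply ``microns_per_pixel``;
    an explicit argument wins, and the convention default of 0.5 um/px is
    used otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # pragma: no cover - delegated to PIL/tifffile
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path} is not an 8-bit RGB image (shape {arr.shape}); "
            "grayscale and alpha images are not supported"
        )
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit samples, got {arr.dtype}")

    if microns_per_pixel is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            microns_per_pixel = float(meta.get("microns_per_pixel", DEFAULT_MICRONS_PER_PIXEL))
        else:
            microns_per_pixel = DEFAULT_MICRONS_PER_PIXEL
    return SlideImage(slide_id=path.stem, pixels=arr, microns_per_pixel=microns_per_pixel)


def save_slide(slide: SlideImage, path: str | Path) -> None:
    """Write a SlideImage as PNG or TIFF, with a metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, slide.pixels, compression="deflate")
    else:
        Image.fromarray(slide.pixels, mode="RGB").save(path)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps({"microns_per_pixel": slide.microns_per_pixel}))


# ---------------------------------------------------------------------------
# annotation I/O (GeoJSON)


def load_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of Polygon features.

    Each feature must carry properties ``class`` (stroma, benign_gland, gp3,
    gp4plus, or exclude) and, for class features, a non-empty ``biopsy_id``.
    Self-intersecting polygons are rejected.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    ann = AnnotationSet()
    for idx, feature in enumerate(data.get("features", [])):
        props = feature.get("properties") or {}
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"feature {idx}: only Polygon geometries are supported")
        if "class" not in props:
            raise ValueError(f"feature {idx}: missing 'class' property")
        rings = geom.get("coordinates") or []
        if not rings:
            raise ValueError(f"feature {idx}: empty polygon")
        # exterior ring only; GeoJSON closes the ring, drop the repeat vertex
        verts = np.asarray(rings[0], dtype=float)
        if len(verts) >= 2 and np.array_equal(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError(f"feature {idx}: polygon has fewer than 3 vertices")
        if not ShapelyPolygon(verts).is_valid:
            raise ValueError(f"feature {idx}: polygon is invalid (self-intersecting?)")
        cls_name = str(props["class"])
        if cls_name.lower() == EXCLUDE_NAME:
            ann.exclusions.append(verts)
            continue
        tissue = TissueClass.from_name(cls_name)  # raises on unknown names
        biopsy_id = props.get("biopsy_id")
        if not biopsy_id:
            raise ValueError(f"feature {idx}: missing or empty 'biopsy_id' property")
        ann.regions.append(AnnotatedRegion(verts, tissue, str(biopsy_id)))
    return ann


def save_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as a GeoJSON FeatureCollection."""

    def _ring(verts: np.ndarray) -> list[list[float]]:
        ring = [[float(x), float(y)] for x, y in verts]
        ring.append(ring[0])
        return ring

    features = []
    for r in ann.regions:
        features.append(
            {
                "type": "Feature",
                "properties": {"class": r.tissue_class.name.lower(), "biopsy_id": r.biopsy_id},
                "geometry": {"type": "Polygon", "coordinates": [_ring(r.polygon)]},
            }
        )
    for verts in ann.exclusions:
        features.append(
            {
                "type": "Feature",
                "properties": {"class": EXCLUDE_NAME},
                "geometry": {"type": "Polygon", "coordinates": [_ring(np.asarray(verts))]},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


# ---------------------------------------------------------------------------
# rasterization


def points_in_polygon(rows: np.ndarray, cols: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd membership test for pixel centers, boundary counted as inside.

    ``rows``/``cols`` are broadcastable integer arrays of pixel coordinates
    (y and x respectively).  Vectorized ray-crossing with an explicit
    point-on-segment check so that boundary pixels are deterministically
    inside.
    """
    polygon = np.asarray(polygon, dtype=float)
    x = np.asarray(cols, dtype=float)
    y = np.asarray(rows, dtype=float)
    inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
    on_edge = np.zeros_like(inside)
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        # ray to +x crossing count (half-open in y to handle vertices once)
        crosses = (y1 > y) != (y2 > y)
        if np.any(crosses):
            x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1) if y1 != y2 else x1
            inside ^= crosses & (x < np.where(crosses, x_at_y, np.inf))
        # on-segment test: zero cross product and inside bounding box
        dx, dy = x2 - x1, y2 - y1
        cross = dx * (y - y1) - dy * (x - x1)
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            on = (np.abs(x - x1) < 1e-9) & (np.abs(y - y1) < 1e-9)
        else:
            t = ((x - x1) * dx + (y - y1) * dy) / seg_len2
            on = (np.abs(cross) < 1e-9 * max(1.0, np.sqrt(seg_len2))) & (t >= 0) & (t <= 1)
        on_edge |= on
    return inside | on_edge


def rasterize(ann: AnnotationSet, height: int, width: int) -> LabelMask:
    """Rasterize annotations to a per-pixel label grid.

    Class polygons paint their TissueClass code (later regions overwrite
    earlier ones where class polygons overlap); exclusion polygons then
    override everything with EXCLUDED; untouched pixels stay UNLABELED.
    """
    grid = np.full((height, width), UNLABELED, dtype=np.int8)
    for region in ann.regions:
        _paint(grid, region.polygon, np.int8(int(region.tissue_class)), height, width)
    for verts in ann.exclusions:
        _paint(grid, np.asarray(verts, dtype=float), np.int8(EXCLUDED), height, width)
    return LabelMask(grid=grid)


def _paint(grid: np.ndarray, polygon: np.ndarray, code: np.int8, height: int, width: int) -> None:
    r0 = max(int(np.floor(polygon[:, 1].min())), 0)
    r1 = min(int(np.ceil(polygon[:, 1].max())), height - 1)
    c0 = max(int(np.floor(polygon[:, 0].min())), 0)
    c1 = min(int(np.ceil(polygon[:, 0].max())), width - 1)
    if r1 < r0 or c1 < c0:
        return
    rr = np.arange(r0, r1 + 1)[:, None]
    cc = np.arange(c0, c1 + 1)[None, :]
    member = points_in_polygon(rr, cc, polygon)
    grid[r0 : r1 + 1, c0 : c1 + 1][member] = code
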