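"""Reading annotated glomeruli, crop extraction and biopsy-level splitting.

Glomeruli are annotated as polygons on a source image (one outline per
glomerulus, labelled sclerotic or non-sclerotic, with biopsy/section
provenance).  Each outline is surrounded by a rectangular bounding box
enlarged by an overestimation factor (1.1 per dimension by default) and the
corresponding sub-image is extracted as the unit of classification.

Train/test splitting is performed at biopsy level: all glomeruli of one
biopsy land on the same side of the split, so that no tissue sample
contributes to both training and evaluation.

Coordinate convention: 0-based pixel coordinates, half-open rectangles
``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

SCLEROTIC = "sclerotic"
NON_SCLEROTIC = "non_sclerotic"
LABELS = (SCLEROTIC, NON_SCLEROTIC)


@dataclass(frozen=True)
class AnnotatedRegion:
    """A polygonal glomerulus outline on a source image."""

    polygon: tuple[tuple[float, float], ...]
    label: str
    biopsy_id: str
    section_id: str = ""
    slide_path: str = ""

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("polygon must have at least 3 vertices")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class GlomerulusCrop:
    """An RGB glomerulus image patch with label and provenance."""

    pixels: np.ndarray  # H x W x 3, uint8
    label: str | None
    biopsy_id: str
    section_id: str = ""
    crop_rect: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1)
    artifact: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class DatasetSplit:
    """Biopsy-disjoint train/test partition of a crop collection."""

    train: list[GlomerulusCrop]
    test: list[GlomerulusCrop]

    @property
    def train_biopsies(self) -> set[str]:
        return {c.biopsy_id for c in self.train}

    @property
    def test_biopsies(self) -> set[str]:
        return {c.biopsy_id for c in self.test}


def expand_bbox(
    region: AnnotatedRegion,
    factor: float,
    image_extent: tuple[int, int],
) -> tuple[int, int, int, int]:
    """Overestimated bounding box of a polygon annotation.

    The tight axis-aligned bounding box of the polygon is scaled by
    ``factor`` per dimension about its center, rounded outward to integer
    pixels and clamped to ``image_extent = (width, height)``.  Returns a
    half-open rectangle ``(x0, y0, x1, y1)``.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    xs = [p[0] for p in region.polygon]
    ys = [p[1] for p in region.polygon]
    x_min, x_max = min(xs), max(xs)
    y_min, y_max = min(ys), max(ys)
    if x_max - x_min <= 0 or y_max - y_min <= 0:
        raise ValueError("degenerate polygon: zero width or height")
    width, height = image_extent

    def _scaled(lo: float, hi: float, limit: int) -> tuple[int, int]:
        center = (lo + hi) / 2.0
        half = (hi - lo) * factor / 2.0
        # outward rounding, with a guard against float noise (1.1 * 200 / 2
        # must not floor 90.0 down to 89)
        a = max(0, math.floor(round(center - half, 9)))
        b = min(limit, math.ceil(round(center + half, 9)))
        return a, b

    x0, x1 = _scaled(x_min, x_max, width)
    y0, y1 = _scaled(y_min, y_max, height)
    return x0, y0, x1, y1


def extract_crop(
    slide_image: np.ndarray,
    rect: tuple[int, int, int, int],
    label: str | None,
    biopsy_id: str,
    section_id: str = "",
) -> GlomerulusCrop:
    """Copy the half-open sub-rectangle of ``slide_image`` into a crop."""
    x0, y0, x1, y1 = rect
    h, w = slide_image.shape[:2]
    for name, val, lo, hi in (
        ("x0", x0, 0, w), ("x1", x1, 0, w), ("y0", y0, 0, h), ("y1", y1, 0, h),
    ):
        if not lo <= val <= hi:
            raise ValueError(
                f"rectangle coordinate {name}={val} outside slide extent "
                f"({w} x {h})"
            )
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty rectangle {rect}")
    pixels = np.ascontiguousarray(slide_image[y0:y1, x0:x1])
    return GlomerulusCrop(
        pixels=pixels.astype(np.uint8, copy=False),
        label=label,
        biopsy_id=biopsy_id,
        section_id=section_id,
        crop_rect=(x0, y0, x1, y1),
    )


def split_by_biopsy(
    crops: list[GlomerulusCrop],
    test_fraction: float,
    seed: int,
    n_candidates: int = 200,
) -> DatasetSplit:
    """Randomized biopsy-level train/test split.

    Whole biopsies are assigned to the test set so that the achieved test
    glomerulus count is as close as possible to ``test_fraction`` of the
    total.  The search draws ``n_candidates`` random biopsy orders, greedily
    accumulates biopsies while the deviation from the target improves, and
    keeps the best assignment.  Deterministic for a fixed ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    by_biopsy: dict[str, list[GlomerulusCrop]] = {}
    for c in crops:
        by_biopsy.setdefault(c.biopsy_id, []).append(c)
    biopsy_ids = sorted(by_biopsy)
    if len(biopsy_ids) < 2:
        raise ValueError("biopsy-level split impossible with a single biopsy")
    sizes = {b: len(by_biopsy[b]) for b in biopsy_ids}
    target = test_fraction * len(crops)

    rng = np.random.default_rng(seed)
    best: tuple[float, tuple[str, ...]] | None = None
    for _ in range(n_candidates):
        order = list(rng.permutation(biopsy_ids))
        chosen: list[str] = []
        count = 0
        for b in order:
            # adding b must move the count closer to the target and
            # must leave at least one biopsy for training
            if len(chosen) + 1 == len(biopsy_ids):
                break
            if abs(count + sizes[b] - target) <= abs(count - target):
                chosen.append(b)
                count += sizes[b]
        if not chosen:  # test set may not be empty
            chosen = [order[0]]
            count = sizes[order[0]]
        key = (abs(count - target), tuple(sorted(chosen)))
        if best is None or key < best:
            best = key
    assert best is not None
    test_ids = set(best[1])
    train = [c for c in crops if c.biopsy_id not in test_ids]
    test = [c for c in crops if c.biopsy_id in test_ids]
    return DatasetSplit(train=train, test=test)


# ---------------------------------------------------------------------------
# Annotation JSON and image files


def read_annotations(path: str | Path) -> list[AnnotatedRegion]:
    """Read a JSON array of polygon annotations.

    Each entry is an object ``{polygon: [[x, y], ...], label, biopsy_id,
    section_id, image}``; ``image`` is resolved relative to the JSON file.
    """
    path = Path(path)
    with open(path) as fh:
        entries = json.load(fh)
    regions = []
    for e in entries:
        slide = e.get("image", "")
        if slide and not Path(slide).is_absolute():
            slide = str(path.parent / slide)
        regions.append(
            AnnotatedRegion(
                polygon=tuple((float(x), float(y)) for x, y in e["polygon"]),
                label=e["label"],
                biopsy_id=str(e["biopsy_id"]),
                section_id=str(e.get("section_id", "")),
                slide_path=slide,
            )
        )
    return regions


def write_annotations(regions: list[AnnotatedRegion], path: str | Path) -> None:
    entries = [
        {
            "polygon": [[float(x), float(y)] for x, y in r.polygon],
            "label": r.label,
            "biopsy_id": r.biopsy_id,
            "section_id": r.section_id,
            "image": r.slide_path,
        }
        for r in regions
    ]
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF) as an H x W x 3 uint8 array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return arr


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def load_crops(
    regions: list[AnnotatedRegion],
    overestimation: float = 1.1,
) -> list[GlomerulusCrop]:
    """Extract the overestimated crop of every annotated region."""
    cache: dict[str, np.ndarray] = {}
    crops = []
    for r in regions:
        if r.slide_path not in cache:
            cache[r.slide_path] = read_image(r.slide_path)
        slide = cache[r.slide_path]
        h, w = slide.shape[:2]
        rect = expand_bbox(r, overestimation, (w, h))
        crops.append(extract_crop(slide, rect, r.label, r.biopsy_id, r.section_id))
    return crops
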