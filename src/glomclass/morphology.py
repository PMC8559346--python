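"""Bowman's-space segmentation and the two morphological features.

The white regions of a PAS-stained glomerulus (Bowman's space, capillary
lumens, inter-capillary gaps) are segmented by three parallel colour-space
procedures that are then fused by a per-pixel majority vote:

1. binarisation of the RGB **green** channel at a fixed threshold (190),
2. binarisation of the **complement of magenta** from a naive CMYK
   conversion at the same threshold,
3. k-means clustering (k=5, 3 restarts) of the CIELAB **(a, b)** plane,
   keeping the cluster with the highest mean grey-level intensity.

Each route is cleaned with median filtering, erosion and dilation (disk
structuring elements) and refined with a region-based active contour
(morphological Chan-Vese, 200 iterations).  After the majority vote,
components smaller than 1000 pixels are dropped and the mask is intersected
with a centred disk of diameter 7/8 of the smaller image dimension, which
removes structures touching the crop border.

Two features summarise the final mask: the white-area fraction (mask area
normalised by image area) and the equivalent radius of the mask's convex
hull (radius of the circle with the same area as the hull).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray, rgb2lab
from skimage.morphology import (
    convex_hull_image,
    dilation,
    disk,
    erosion,
    remove_small_objects,
)
from skimage.segmentation import morphological_chan_vese
from sklearn.cluster import KMeans

from .image_io import GlomerulusCrop

logger = logging.getLogger(__name__)

RGB_GREEN = "rgb_green"
CMYK_MAGENTA_COMPLEMENT = "cmyk_magenta_complement"

#: default whiteness threshold on 8-bit channels
WHITE_THRESHOLD = 190
#: default active-contour iteration count
AC_ITERATIONS = 200
#: default minimum connected-component area (pixels)
MIN_REGION_PX = 1000


@dataclass(frozen=True)
class MorphologicalFeatures:
    white_area_fraction: float  # mask area / image area, in [0, 1]
    equivalent_radius: float    # pixels, from the convex-hull area


def magenta_complement(pixels: np.ndarray) -> np.ndarray:
    """``255 * (1 - M)`` with M from the naive device CMYK conversion.

    K = 1 - max(R, G, B)/255 and M = (1 - G/255 - K)/(1 - K); M is defined
    as 0 where K = 1 (pure black).
    """
    rgb = pixels.astype(float) / 255.0
    k = 1.0 - rgb.max(axis=2)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom > 0, (1.0 - rgb[..., 1] - k) / denom, 0.0)
    return 255.0 * (1.0 - m)


def _clean(mask: np.ndarray, radius: int) -> np.ndarray:
    """Median filter, erosion, dilation with a disk structuring element."""
    selem = disk(radius)
    cleaned = ndimage.median_filter(mask.astype(np.uint8), footprint=selem).astype(bool)
    cleaned = erosion(cleaned, selem)
    return dilation(cleaned, selem)


def _active_contour(channel: np.ndarray, init: np.ndarray, iterations: int) -> np.ndarray:
    """Region-based (Chan-Vese) refinement of a binary mask on a channel image.

    The contour is initialised with the mask; the bright phase is returned.
    Empty or full initialisations are fixed points and are returned as-is.
    """
    if iterations <= 0 or not init.any() or init.all():
        return init
    seg = morphological_chan_vese(
        channel.astype(float), num_iter=iterations, init_level_set=init.astype(np.int8)
    ).astype(bool)
    if not seg.any() or seg.all():
        return seg
    # Chan-Vese labels phases arbitrarily; keep the brighter one
    if channel[seg].mean() < channel[~seg].mean():
        seg = ~seg
    return seg


def white_mask_from_channel(
    crop: GlomerulusCrop | np.ndarray,
    channel: str,
    threshold: int = WHITE_THRESHOLD,
    clean_radius: int = 2,
    ac_iterations: int = AC_ITERATIONS,
) -> np.ndarray:
    """White-region mask from a single colour channel.

    ``channel`` selects the RGB green plane or the complement-of-magenta
    plane; pixels with channel value >= ``threshold`` are kept, then cleaned
    and refined by active contour.
    """
    pixels = crop.pixels if isinstance(crop, GlomerulusCrop) else np.asarray(crop)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    if not 1 <= clean_radius <= 3:
        raise ValueError("clean_radius must be in [1, 3]")
    if channel == RGB_GREEN:
        plane = pixels[..., 1].astype(float)
    elif channel == CMYK_MAGENTA_COMPLEMENT:
        plane = magenta_complement(pixels)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    raw = plane >= threshold
    cleaned = _clean(raw, clean_radius)
    return _active_contour(plane, cleaned, ac_iterations)


def binarize_channel(pixels: np.ndarray, channel: str, threshold: int = WHITE_THRESHOLD) -> np.ndarray:
    """Raw thresholding step only (before cleaning), exposed for auditing."""
    if channel == RGB_GREEN:
        plane = pixels[..., 1].astype(float)
    else:
        plane = magenta_complement(pixels)
    return plane >= threshold


def lab_cluster_mask(
    crop: GlomerulusCrop | np.ndarray,
    k: int = 5,
    replicates: int = 3,
    clean_radius: int = 2,
    ac_iterations: int = AC_ITERATIONS,
    rng_state: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """White-region mask from k-means clustering of the CIELAB (a, b) plane.

    k-means (best of ``replicates`` restarts by within-cluster sum of
    squares) partitions the chromaticity plane; the retained cluster is the
    one with the greatest mean grey-scale intensity of the original crop.
    Cleaning and active-contour refinement (on the grey-scale image) follow.
    """
    pixels = crop.pixels if isinstance(crop, GlomerulusCrop) else np.asarray(crop)
    lab = rgb2lab(pixels)
    ab = lab[..., 1:].reshape(-1, 2)
    gray = rgb2gray(pixels)  # luminance in [0, 1]

    n_distinct = np.unique(ab, axis=0).shape[0]
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.warning("only %d distinct (a, b) values; reducing k from %d", n_distinct, k)
    if k_eff == 1:
        return np.ones(pixels.shape[:2], dtype=bool)

    seed = rng_state if isinstance(rng_state, (int, np.integer)) else (
        int(rng_state.integers(2**31)) if rng_state is not None else None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-means may converge early
        km = KMeans(n_clusters=k_eff, n_init=replicates, random_state=seed).fit(ab)
    labels = km.labels_.reshape(pixels.shape[:2])
    means = ndimage.mean(gray, labels=labels, index=np.arange(k_eff))
    mask = labels == int(np.argmax(means))
    cleaned = _clean(mask, clean_radius)
    return _active_contour(gray * 255.0, cleaned, ac_iterations)


def centered_disk(shape: tuple[int, int]) -> np.ndarray:
    """Centred disk of diameter 7/8 of the smaller image dimension."""
    h, w = shape
    radius = (7.0 / 8.0) * min(h, w) / 2.0
    yy, xx = np.mgrid[:h, :w]
    return (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2 <= radius**2


def fuse_and_filter(
    m1: np.ndarray,
    m2: np.ndarray,
    m3: np.ndarray,
    min_region: int = MIN_REGION_PX,
    image_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Majority-vote fusion of three masks, small-region removal, disk AND.

    A pixel survives the vote iff it is set in at least two of the three
    masks.  Connected components (8-connectivity) smaller than
    ``min_region`` pixels are removed, and the result is intersected with
    the centred 7/8 disk.
    """
    if not (m1.shape == m2.shape == m3.shape):
        raise ValueError(
            f"mask extents differ: {m1.shape}, {m2.shape}, {m3.shape}"
        )
    if image_shape is not None and tuple(image_shape) != m1.shape:
        raise ValueError(f"masks {m1.shape} do not match image {tuple(image_shape)}")
    fused = (m1.astype(np.uint8) + m2.astype(np.uint8) + m3.astype(np.uint8)) >= 2
    # drop components with area < min_region (i.e. area <= min_region - 1)
    fused = remove_small_objects(fused, connectivity=2, max_size=min_region - 1)
    return fused & centered_disk(fused.shape)


def segment_white_regions(
    crop: GlomerulusCrop | np.ndarray,
    threshold: int = WHITE_THRESHOLD,
    clean_radius: int = 2,
    ac_iterations: int = AC_ITERATIONS,
    kmeans_k: int = 5,
    kmeans_replicates: int = 3,
    min_region_px: int = MIN_REGION_PX,
    rng_state: int | None = 0,
) -> np.ndarray:
    """Full segmentation workflow: three colour-space masks fused and filtered."""
    m_green = white_mask_from_channel(
        crop, RGB_GREEN, threshold, clean_radius, ac_iterations
    )
    m_magenta = white_mask_from_channel(
        crop, CMYK_MAGENTA_COMPLEMENT, threshold, clean_radius, ac_iterations
    )
    m_lab = lab_cluster_mask(
        crop, kmeans_k, kmeans_replicates, clean_radius, ac_iterations, rng_state
    )
    return fuse_and_filter(m_green, m_magenta, m_lab, min_region_px)


def morphological_features(final_mask: np.ndarray) -> MorphologicalFeatures:
    """White-area fraction and convex-hull equivalent radius of a mask."""
    mask = np.asarray(final_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return MorphologicalFeatures(0.0, 0.0)
    area_fraction = float(mask.sum()) / mask.size
    hull_area = float(convex_hull_image(mask).sum())
    radius = float(np.sqrt(hull_area / np.pi))
    return MorphologicalFeatures(area_fraction, radius)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Export an intermediate mask as a 1-bit PNG for visual audit."""
    from PIL import Image

    Image.fromarray(np.asarray(mask, dtype=bool)).save(path, bits=1)
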