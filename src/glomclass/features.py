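"""The 150-value glomerulus descriptor as a scikit-learn transformer.

Per crop: 2 morphological features (white-area fraction, convex-hull
equivalent radius), 120 mrcLBP values and 28 direction-reduced Haralick
values, in that order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import morphology, texture
from .image_io import GlomerulusCrop

N_MORPH = 2
N_LBP = 120
N_HARALICK = 28
N_FEATURES = N_MORPH + N_LBP + N_HARALICK  # 150


def feature_names() -> list[str]:
    names = ["morph_area", "morph_radius"]
    for ch in texture.CHANNELS:
        for r in texture.LBP_RADII:
            names += [f"lbp_{ch}_{r}_{b}" for b in range(texture.LBP_BINS)]
    names += [f"har_mean_{n}" for n in texture.HARALICK_NAMES]
    names += [f"har_range_{n}" for n in texture.HARALICK_NAMES]
    return names


class GlomerulusFeatureExtractor(TransformerMixin, BaseEstimator):
    """Compute the 150-feature descriptor for a sequence of crops.

    Stateless (``fit`` only records the output width), so it can sit at the
    head of a scikit-learn :class:`~sklearn.pipeline.Pipeline` whose ``X``
    is a list of :class:`~glomclass.image_io.GlomerulusCrop`.

    Parameters mirror the segmentation and texture stages; defaults are the
    workflow's empirically fixed values (whiteness threshold 190, 200
    active-contour iterations, k-means with k=5 and 3 restarts, 1000-pixel
    minimum region, GLCM distance 1 at 64 grey levels).
    """

    def __init__(
        self,
        threshold: int = morphology.WHITE_THRESHOLD,
        clean_radius: int = 2,
        ac_iterations: int = morphology.AC_ITERATIONS,
        kmeans_k: int = 5,
        kmeans_replicates: int = 3,
        min_region_px: int = morphology.MIN_REGION_PX,
        glcm_distance: int = 1,
        glcm_levels: int = 64,
        random_state: int = 0,
    ):
        self.threshold = threshold
        self.clean_radius = clean_radius
        self.ac_iterations = ac_iterations
        self.kmeans_k = kmeans_k
        self.kmeans_replicates = kmeans_replicates
        self.min_region_px = min_region_px
        self.glcm_distance = glcm_distance
        self.glcm_levels = glcm_levels
        self.random_state = random_state

    def fit(self, X: Sequence[GlomerulusCrop], y=None):
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: Sequence[GlomerulusCrop]) -> np.ndarray:
        rows = [self._extract_one(crop) for crop in X]
        return np.vstack(rows) if rows else np.empty((0, N_FEATURES))

    def _extract_one(self, crop: GlomerulusCrop | np.ndarray) -> np.ndarray:
        pixels = crop.pixels if isinstance(crop, GlomerulusCrop) else np.asarray(crop)
        mask = morphology.segment_white_regions(
            pixels,
            threshold=self.threshold,
            clean_radius=self.clean_radius,
            ac_iterations=self.ac_iterations,
            kmeans_k=self.kmeans_k,
            kmeans_replicates=self.kmeans_replicates,
            min_region_px=self.min_region_px,
            rng_state=self.random_state,
        )
        morph = morphology.morphological_features(mask)
        lbp = texture.mrclbp_features(pixels)
        har = texture.haralick_block(
            texture.luminance(pixels), self.glcm_distance, self.glcm_levels
        )
        return np.concatenate([[morph.white_area_fraction, morph.equivalent_radius], lbp, har])

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_features_out_")
        return np.asarray(feature_names(), dtype=object)


def extract_feature_table(
    crops: Iterable[GlomerulusCrop], **params
) -> pd.DataFrame:
    """Feature table with one row per crop: 150 named feature columns plus
    ``label``, ``biopsy_id``, ``section_id`` and ``artifact`` provenance."""
    crops = list(crops)
    X = GlomerulusFeatureExtractor(**params).fit(crops).transform(crops)
    df = pd.DataFrame(X, columns=feature_names())
    df["label"] = [c.label for c in crops]
    df["biopsy_id"] = [c.biopsy_id for c in crops]
    df["section_id"] = [c.section_id for c in crops]
    df["artifact"] = [c.artifact for c in crops]
    return df
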