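"""Texture descriptors: multi-radial colour LBP and Haralick GLCM features.

**mrcLBP** applies rotation-invariant uniform local binary patterns (8
circularly interpolated neighbours, ``riu2`` mapping) to each RGB channel at
radii 1, 3, 9 and 27.  Each (channel, radius) pair yields a 10-bin
normalised histogram (9 uniform codes + 1 non-uniform bin), for 120 values.

**Haralick features** are computed from grey-level co-occurrence matrices at
the four standard directions (0deg, 45deg, 90deg, 135deg).  The 14 classic
indices are evaluated per direction (56 values) and reduced to the mean and
the range over directions (28 values).  The grey image is the Rec. 601
luminance quantised to 64 levels; the co-occurrence distance is 1 pixel.
Both choices are configurable.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix, local_binary_pattern

from .image_io import GlomerulusCrop

LBP_RADII = (1, 3, 9, 27)
LBP_NEIGHBORS = 8
LBP_BINS = LBP_NEIGHBORS + 2  # riu2: codes 0..P, plus the non-uniform bin
CHANNELS = ("r", "g", "b")

GLCM_DIRECTIONS = (0, 45, 90, 135)
# standard GLCM directions measured on the image grid: 45deg pairs each pixel
# with its upper-right neighbour (row - d, col + d).  skimage's angle walks
# clockwise on the (row, col) grid, so 45deg maps to 3*pi/4 and vice versa.
_DIRECTION_ANGLES = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}

HARALICK_NAMES = (
    "asm",                # angular second moment
    "contrast",
    "correlation",
    "variance",           # sum of squares: variance
    "idm",                # inverse difference moment
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",               # information measure of correlation 1
    "imc2",               # information measure of correlation 2
    "mcc",                # maximal correlation coefficient
)


def lbp_riu_histogram(
    channel_image: np.ndarray, radius: int, neighbors: int = LBP_NEIGHBORS
) -> np.ndarray:
    """Normalised riu2 LBP histogram of one channel at one radius.

    Neighbours are sampled on a circle with bilinear interpolation and
    compared against the centre; uniform codes map to their bit count
    (0..P), non-uniform codes to a single extra bin.  Border pixels without
    a complete neighbourhood are excluded, and the histogram is normalised
    by the number of coded pixels.
    """
    img = np.asarray(channel_image)
    if img.ndim != 2:
        raise ValueError("channel image must be 2-D")
    if min(img.shape) <= 2 * radius + 1:
        raise ValueError(
            f"image {img.shape} too small for LBP radius {radius} "
            f"(needs more than {2 * radius + 1} pixels per side)"
        )
    codes = local_binary_pattern(img, neighbors, radius, method="uniform")
    interior = codes[radius:-radius, radius:-radius]
    hist = np.bincount(interior.astype(int).ravel(), minlength=neighbors + 2)
    return hist / hist.sum()


def mrclbp_features(crop: GlomerulusCrop | np.ndarray) -> np.ndarray:
    """The 120-value multi-radial colour LBP block.

    Order: channel-major (R, G, B), radius-minor (1, 3, 9, 27), 10 histogram
    bins per (channel, radius) pair.
    """
    pixels = crop.pixels if isinstance(crop, GlomerulusCrop) else np.asarray(crop)
    min_size = 2 * max(LBP_RADII) + 1
    if min(pixels.shape[:2]) <= min_size:
        raise ValueError(
            f"crop {pixels.shape[:2]} too small for mrcLBP; "
            f"needs more than {min_size} pixels per side"
        )
    blocks = [
        lbp_riu_histogram(pixels[..., c], r)
        for c in range(3)
        for r in LBP_RADII
    ]
    return np.concatenate(blocks)


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an 8-bit RGB image, in [0, 255]."""
    rgb = np.asarray(pixels, dtype=float)
    return 0.2989 * rgb[..., 0] + 0.5870 * rgb[..., 1] + 0.1140 * rgb[..., 2]


def quantize(gray: np.ndarray, levels: int = 64) -> np.ndarray:
    """Quantise a [0, 255] grey image to ``levels`` equal-width bins."""
    g = np.clip(np.asarray(gray, dtype=float), 0, 255)
    return np.minimum((g * levels / 256.0).astype(np.intp), levels - 1)


def glcm(
    gray: np.ndarray, direction: int, distance: int = 1, levels: int = 64
) -> np.ndarray:
    """Normalised symmetric grey-level co-occurrence matrix for one direction.

    ``gray`` may be an 8-bit image (quantised here) or an already quantised
    integer image with values below ``levels``.  Pairs are counted in both
    orders and the matrix is normalised to sum 1.
    """
    if direction not in _DIRECTION_ANGLES:
        raise ValueError(f"direction must be one of {GLCM_DIRECTIONS}")
    g = np.asarray(gray)
    if g.dtype.kind == "f" or g.max() >= levels:
        g = quantize(g, levels)
    if min(g.shape) <= distance:
        raise ValueError(f"image {g.shape} smaller than GLCM distance {distance}")
    p = graycomatrix(
        g.astype(np.uint8),
        distances=[distance],
        angles=[_DIRECTION_ANGLES[direction]],
        levels=levels,
        symmetric=True,
        normed=True,
    )[:, :, 0, 0]
    return p


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy with the 0 * log(0) = 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick14(P: np.ndarray) -> np.ndarray:
    """The 14 classic Haralick statistics of a normalised co-occurrence matrix.

    Order: angular second moment, contrast, correlation, variance (sum of
    squares), inverse difference moment, sum average, sum variance, sum
    entropy, entropy, difference variance, difference entropy, the two
    information measures of correlation, and the maximal correlation
    coefficient.  Logarithms use the 0*log(0)=0 convention; correlation-type
    features of degenerate (single-level) matrices are defined as 0, and the
    maximal correlation coefficient falls back to 0 if not finite.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError(f"matrix not normalised (sum = {P.sum():.6g})")
    n = P.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # distributions of i+j (range 0..2n-2) and |i-j| (range 0..n-1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    ks = np.arange(2 * n - 1)
    kd = np.arange(n)

    asm = float((P**2).sum())
    contrast = float((kd**2 * p_diff).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    entropy = _entropy(P.ravel())
    diff_mean = float((kd * p_diff).sum())
    difference_variance = float(((kd - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    hxy = entropy
    pxy = np.outer(px, py)
    log_pxy = np.zeros_like(pxy)
    nzm = pxy > 0
    log_pxy[nzm] = np.log(pxy[nzm])
    hxy1 = float(-(P * log_pxy).sum())
    hxy2 = float(-(pxy[nzm] * log_pxy[nzm]).sum())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i, j) = sum_k P(i,k) P(j,k) / (px(i) py(k))
    nz = (px > 0) & (py > 0)
    mcc = 0.0
    if nz.sum() >= 2:
        Pr = P[np.ix_(nz, nz)]
        pxr, pyr = px[nz], py[nz]
        Q = (Pr / pxr[:, None]) @ (Pr / pyr[None, :]).T
        eig = np.linalg.eigvals(Q)
        eig = np.sort(np.real(eig))[::-1]
        if len(eig) >= 2 and np.isfinite(eig[1]) and eig[1] > 0:
            mcc = float(np.sqrt(eig[1]))
    if not np.isfinite(mcc):
        mcc = 0.0

    return np.array([
        asm, contrast, correlation, variance, idm, sum_average, sum_variance,
        sum_entropy, entropy, difference_variance, difference_entropy,
        imc1, imc2, mcc,
    ])


def haralick_directional(gray: np.ndarray, distance: int = 1, levels: int = 64) -> np.ndarray:
    """4 x 14 matrix of Haralick indices, one row per direction."""
    return np.stack([
        haralick14(glcm(gray, d, distance, levels)) for d in GLCM_DIRECTIONS
    ])


def haralick_block(gray: np.ndarray, distance: int = 1, levels: int = 64) -> np.ndarray:
    """The 28-value Haralick block: 14 directional means then 14 ranges."""
    per_dir = haralick_directional(gray, distance, levels)
    means = per_dir.mean(axis=0)
    ranges = per_dir.max(axis=0) - per_dir.min(axis=0)
    return np.concatenate([means, ranges])
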