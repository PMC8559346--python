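"""Synthetic PAS-stained glomerulus crops.

The generator emulates the visual structure that drives the classification:

* **non-sclerotic** glomeruli: an elliptic capsule delimited by a thin
  membrane, a near-white annular Bowman's space between capsule and tuft,
  white capillary lumens inside the tuft, small dark-blue nuclei and a
  pink-magenta mesangial matrix with low-frequency mottling (the
  "pomegranate texture");
* **sclerotic** glomeruli: the capsule interior is filled by a homogeneous
  pink-magenta extracellular matrix, lumens are obliterated (at most one
  small remnant), the Bowman's space is absent and nuclei are sparse.

Each simulated biopsy carries its own colour/saturation profile so that the
dataset shows the wide stain-intensity variability of real slide batches.
Classes are imbalanced (about 5.5 non-sclerotic per sclerotic by default).

All colours are chosen to straddle the fixed whiteness threshold of 190
used by the segmentation stage: white structures stay above it under any
biopsy profile, tissue stays below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import NON_SCLEROTIC, SCLEROTIC, GlomerulusCrop

MATRIX_RGB = np.array([200.0, 120.0, 160.0])      # mesangial / sclerotic matrix
SCLEROTIC_MATRIX_RGB = np.array([205.0, 140.0, 175.0])
NUCLEUS_RGB = np.array([60.0, 60.0, 140.0])
WHITE_RGB = np.array([242.0, 242.0, 242.0])       # Bowman's space, lumens
BACKGROUND_RGB = np.array([230.0, 140.0, 200.0])  # surrounding tubular tissue
CAPSULE_RGB = np.array([175.0, 95.0, 135.0])      # capsule membrane


@dataclass(frozen=True)
class SynthesisParams:
    """Configuration of the synthetic dataset generator."""

    image_size: int = 112
    glomerulus_radius_range: tuple[int, int] = (30, 38)
    class_ratio: float = 5.5          # non-sclerotic per sclerotic
    n_biopsies: int = 10
    glomeruli_per_biopsy: int = 30
    saturation_jitter: float = 0.4    # relative stain-density spread across biopsies
    artifact_rate: float = 0.0        # fraction of crops with edge cuts / stain blobs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.n_biopsies <= 0 or self.glomeruli_per_biopsy <= 0:
            raise ValueError("counts and sizes must be positive")
        if self.class_ratio <= 0:
            raise ValueError("class_ratio must be positive")
        if not 0 <= self.saturation_jitter <= 1:
            raise ValueError("saturation_jitter must be in [0, 1]")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        # the capsule (tuft radius + annulus + membrane) must fit the image
        if self.image_size < 2 * (self.glomerulus_radius_range[1] + 12):
            raise ValueError(
                f"image_size {self.image_size} too small for maximum glomerulus "
                f"radius {self.glomerulus_radius_range[1]}"
            )


@dataclass(frozen=True)
class BiopsyProfile:
    """Per-biopsy stain appearance: colour offsets and saturation scale."""

    saturation: float
    matrix_shift: np.ndarray
    background_shift: np.ndarray


def _sample_profile(params: SynthesisParams, rng: np.random.Generator) -> BiopsyProfile:
    half = params.saturation_jitter / 2.0
    return BiopsyProfile(
        saturation=1.0 + rng.uniform(-half, half),
        matrix_shift=rng.uniform(-12, 12, size=3),
        background_shift=rng.uniform(-10, 10, size=3),
    )


def _stained(base: np.ndarray, profile: BiopsyProfile, shift: np.ndarray | None = None) -> np.ndarray:
    """Apply a biopsy saturation profile to a base colour.

    Saturation acts on stain density (distance from white), so a weakly
    stained biopsy is uniformly paler, never darker than white.
    """
    colour = base + (shift if shift is not None else 0.0)
    return np.clip(255.0 - (255.0 - colour) * profile.saturation, 0, 255)


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, scale: int = 8) -> np.ndarray:
    """Low-frequency multiplicative mottling field in [-1, 1]."""
    coarse = rng.standard_normal((shape[0] // scale + 2, shape[1] // scale + 2))
    fine = ndimage.zoom(coarse, scale, order=1)[: shape[0], : shape[1]]
    return np.clip(fine / 2.5, -1, 1)


def _ellipse_mask(shape, cy, cx, a, b, theta):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    c, s = np.cos(theta), np.sin(theta)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_glomerulus(
    class_label: str,
    params: SynthesisParams,
    rng: np.random.Generator,
    profile: BiopsyProfile | None = None,
    biopsy_id: str = "B00",
    section_id: str = "S0",
) -> GlomerulusCrop:
    """Render one labelled glomerulus crop.

    Deterministic given the state of ``rng``.  ``profile`` carries the
    biopsy-level stain appearance; if omitted, one is drawn from ``rng``.
    """
    if class_label not in (SCLEROTIC, NON_SCLEROTIC):
        raise ValueError(f"unknown class label {class_label!r}")
    if profile is None:
        profile = _sample_profile(params, rng)
    n = params.image_size
    sclerotic = class_label == SCLEROTIC

    # geometry: tuft ellipse + annular Bowman's space + capsule membrane
    r_lo, r_hi = params.glomerulus_radius_range
    a = rng.uniform(r_lo, r_hi)                    # tuft semi-major axis
    b = a * rng.uniform(0.78, 0.98)                # tuft semi-minor axis
    theta = rng.uniform(0, np.pi)
    space_w = rng.uniform(6.0, 9.0)                # Bowman's space width
    membrane_w = 2.0
    artifact = rng.random() < params.artifact_rate
    edge_cut = artifact and rng.random() < 0.5
    cy = n / 2 + rng.uniform(-3, 3)
    cx = n / 2 + rng.uniform(-3, 3)
    if edge_cut:  # partial section: glomerulus truncated by the image border
        cy += rng.choice([-1, 1]) * a * rng.uniform(0.6, 0.9)

    tuft = _ellipse_mask((n, n), cy, cx, a, b, theta)
    capsule_in = _ellipse_mask((n, n), cy, cx, a + space_w, b + space_w, theta)
    capsule_out = _ellipse_mask(
        (n, n), cy, cx, a + space_w + membrane_w, b + space_w + membrane_w, theta
    )

    img = np.empty((n, n, 3))
    img[:] = _stained(BACKGROUND_RGB, profile, profile.background_shift)
    # faint tubule texture in the background
    img += (_smooth_noise((n, n), rng, scale=6) * 10.0)[..., None]

    img[capsule_out] = _stained(CAPSULE_RGB, profile, profile.matrix_shift)

    if sclerotic:
        # obliterated glomerulus: matrix fills the whole capsule, no space
        matrix = _stained(SCLEROTIC_MATRIX_RGB, profile, profile.matrix_shift)
        interior = capsule_in
        img[interior] = matrix
        mottle = _smooth_noise((n, n), rng, scale=10) * 6.0
        img[interior] += mottle[interior, None]
        n_lumens = int(rng.random() < 0.3)
        lumen_region = interior
        n_nuclei = rng.integers(3, 10)
    else:
        white = _stained(WHITE_RGB, profile)
        img[capsule_in] = white                     # Bowman's space annulus
        matrix = _stained(MATRIX_RGB, profile, profile.matrix_shift)
        img[tuft] = matrix
        mottle = _smooth_noise((n, n), rng, scale=7) * 14.0
        img[tuft] += mottle[tuft, None]             # pomegranate mottling
        n_lumens = rng.integers(6, 13)
        lumen_region = tuft
        n_nuclei = rng.integers(25, 46)

    yy, xx = np.mgrid[:n, :n]
    white = _stained(WHITE_RGB, profile)
    for _ in range(n_lumens):
        ly, lx, lr = _random_blob_in(lumen_region, rng, 2.0, 5.0)
        if ly is None:
            continue
        img[(yy - ly) ** 2 + (xx - lx) ** 2 <= lr**2] = white

    nucleus = _stained(NUCLEUS_RGB, profile)
    region = tuft if not sclerotic else capsule_in
    for _ in range(n_nuclei):
        ny_, nx_, nr_ = _random_blob_in(region, rng, 1.0, 2.2)
        if ny_ is None:
            continue
        img[(yy - ny_) ** 2 + (xx - nx_) ** 2 <= nr_**2] = nucleus

    if artifact and not edge_cut:  # dark stain blob artefact
        by, bx = rng.uniform(0, n, 2)
        br = rng.uniform(4, 9)
        img[(yy - by) ** 2 + (xx - bx) ** 2 <= br**2] = _stained(
            np.array([120.0, 60.0, 100.0]), profile
        )

    img += rng.normal(0, 3.5, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return GlomerulusCrop(
        pixels=pixels,
        label=class_label,
        biopsy_id=biopsy_id,
        section_id=section_id,
        crop_rect=(0, 0, n, n),
        artifact=artifact,
    )


def _random_blob_in(region: np.ndarray, rng: np.random.Generator, r_lo: float, r_hi: float):
    """Centre and radius of a small disk inside ``region`` (rejection sampling)."""
    n = region.shape[0]
    for _ in range(40):
        y, x = rng.uniform(0, n, 2)
        if region[min(int(y), n - 1), min(int(x), n - 1)]:
            return y, x, rng.uniform(r_lo, r_hi)
    return None, None, None


def _class_counts(params: SynthesisParams) -> list[int]:
    """Per-biopsy sclerotic counts matching the global class ratio.

    Largest-remainder allocation: the global sclerotic total is
    ``round(total / (1 + ratio))`` and is spread as evenly as possible over
    biopsies, so the realised ratio never drifts with sampling noise.
    """
    total = params.n_biopsies * params.glomeruli_per_biopsy
    n_sclerotic = int(round(total / (1.0 + params.class_ratio)))
    base, extra = divmod(n_sclerotic, params.n_biopsies)
    counts = [base] * params.n_biopsies
    for i in range(extra):
        counts[i] += 1
    return counts


def generate_dataset(params: SynthesisParams) -> list[GlomerulusCrop]:
    """Generate the full labelled dataset described by ``params``.

    Each biopsy receives its own stain profile; crops within a biopsy are
    spread over up to four sections.  Reproducible from ``params.seed``.
    """
    root = np.random.SeedSequence(params.seed)
    biopsy_seeds = root.spawn(params.n_biopsies)
    alloc_rng = np.random.default_rng(root.spawn(1)[0])
    counts = _class_counts(params)
    alloc_rng.shuffle(counts)

    crops: list[GlomerulusCrop] = []
    for i, (n_scl, seq) in enumerate(zip(counts, biopsy_seeds)):
        rng = np.random.default_rng(seq)
        profile = _sample_profile(params, rng)
        labels = [SCLEROTIC] * n_scl + [NON_SCLEROTIC] * (
            params.glomeruli_per_biopsy - n_scl
        )
        rng.shuffle(labels)
        n_sections = int(rng.integers(1, 5))
        for j, lab in enumerate(labels):
            crops.append(
                generate_glomerulus(
                    lab,
                    params,
                    rng,
                    profile=profile,
                    biopsy_id=f"B{i:02d}",
                    section_id=f"S{j % n_sections}",
                )
            )
    return crops
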