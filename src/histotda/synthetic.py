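"""Synthetic gland-architecture images for exercising the pipeline.

Prostate adenocarcinoma architecture in a 2-D H&E section reduces, for the
purposes of sublevel-set topology, to arrangements of dark (hematoxylin
stained) nuclei in a bright field: well-circumscribed glands are rings of
nuclei around an empty lumen, cribriform masses are large nuclear sheets
with several punched-out lumina, poorly formed glands are incomplete
rings, solid sheets tile nuclei with minimal gaps, and single-cell
infiltration scatters isolated nuclei through stroma.  This module renders
those seven idealised patterns as grayscale images (low values = nuclei,
matching the post-deconvolution hematoxylin convention) and, through a
known Beer-Lambert stain-mixing model, as pseudo-H&E RGB images so the
deconvolution stage has a ground truth.

The geometry is parametric and deliberately simple: nuclei are truncated
Gaussian bumps (radius = 2 sigma), glands are placed by rejection sampling
with a pattern-dependent minimum centre distance, and all randomness flows
from a single integer seed, so identical specs yield bit-identical images.
Defaults live in :data:`DEFAULT_GEOMETRY` (tuned so that a loose-gland
image produces one dominant loop per gland, small loops from nuclear
arrangement and large loops from glandular lumina).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .stain import CANONICAL_HE, StainMatrix

__all__ = [
    "Pattern",
    "GleasonLabel",
    "ArchitectureSpec",
    "LabeledImage",
    "GeometryError",
    "default_spec",
    "generate_roi",
    "compose_pseudo_he",
    "gray_to_concentration",
    "pseudo_he_from_gray",
    "plan_dataset",
    "generate_dataset",
]


class Pattern(str, Enum):
    LOOSE_GLANDS = "loose_glands"
    CROWDED_GLANDS = "crowded_glands"
    CRIBRIFORM = "cribriform"
    FUSED = "fused"
    POORLY_FORMED = "poorly_formed"
    SOLID_SHEET = "solid_sheet"
    SINGLE_CELL = "single_cell"


class GleasonLabel(str, Enum):
    G3 = "G3"
    G4 = "G4"
    G5 = "G5"


#: Pattern taxonomy: which Gleason grade each architecture belongs to.
PATTERN_GRADE: dict[Pattern, GleasonLabel] = {
    Pattern.LOOSE_GLANDS: GleasonLabel.G3,
    Pattern.CROWDED_GLANDS: GleasonLabel.G3,
    Pattern.CRIBRIFORM: GleasonLabel.G4,
    Pattern.FUSED: GleasonLabel.G4,
    Pattern.POORLY_FORMED: GleasonLabel.G4,
    Pattern.SOLID_SHEET: GleasonLabel.G5,
    Pattern.SINGLE_CELL: GleasonLabel.G5,
}

#: Patterns used for each class when composing a dataset.
CLASS_PATTERNS: dict[GleasonLabel, list[Pattern]] = {
    GleasonLabel.G3: [Pattern.LOOSE_GLANDS, Pattern.CROWDED_GLANDS],
    GleasonLabel.G4: [Pattern.CRIBRIFORM, Pattern.FUSED, Pattern.POORLY_FORMED],
    GleasonLabel.G5: [Pattern.SOLID_SHEET, Pattern.SINGLE_CELL],
}

#: Tuned geometric defaults, expressed at a 512-px reference frame and
#: scaled linearly with image size.  These are generator choices, not
#: measured histology.
DEFAULT_GEOMETRY = {
    "background": 0.92,
    "gland_radius_mean": 55.0,
    "gland_radius_sd": 5.0,
    "nucleus_radius": 8.0,          # truncation radius = 2 sigma
    "nucleus_peak": 0.85,
    "ring_spacing_sigma": 2.2,      # centre spacing of ring nuclei, in sigma
    "sheet_spacing_sigma": 2.2,     # grid spacing in solid sheets / masses
    "min_dist_factor": {            # minimum gland centre distance, in radii
        Pattern.LOOSE_GLANDS: 2.9,
        Pattern.CROWDED_GLANDS: 2.15,
        Pattern.FUSED: 1.45,
    },
    "n_glands": {
        Pattern.LOOSE_GLANDS: 4,
        Pattern.CROWDED_GLANDS: 6,
        Pattern.FUSED: 5,
        Pattern.POORLY_FORMED: 7,
    },
    "stromal_nuclei_density": 2e-5,  # per px^2
    "single_cell_density": 2e-4,
    "background_noise_sd": 0.01,
    "cribriform_lumina": 4,
}


class GeometryError(ValueError):
    """Raised when the requested glands cannot be placed in the frame."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Parameters of one synthetic region of interest."""

    pattern: Pattern
    image_size: int = 512
    n_glands: int = 4
    gland_radius: tuple[float, float] = (55.0, 5.0)   # (mean, sd) px
    nuclei_per_gland: int | None = None               # None = from ring spacing
    nucleus_radius: float = 8.0                       # truncation radius (= 2 sigma)
    nucleus_peak: float = 0.85                        # bump depth, in (0, 1]
    stromal_nuclei_density: float = 2e-5
    background_noise_sd: float = 0.01
    lumina: int = 4                                   # cribriform lumina count
    seed: int = 0
    background: float = field(default=DEFAULT_GEOMETRY["background"])

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if self.gland_radius[0] <= 0 or self.nucleus_radius <= 0:
            raise ValueError("all radii must be positive")
        if not (0 < self.nucleus_peak <= 1):
            raise ValueError("nucleus_peak must lie in (0, 1]")
        if self.stromal_nuclei_density < 0 or self.background_noise_sd < 0:
            raise ValueError("densities and noise must be non-negative")
        if self.n_glands < 0 or (self.nuclei_per_gland is not None
                                 and self.nuclei_per_gland < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LabeledImage:
    """A generated image together with its grade label and source pattern."""

    image: np.ndarray
    label: GleasonLabel
    pattern: Pattern
    spec: ArchitectureSpec


def default_spec(pattern: Pattern | str, image_size: int = 512,
                 seed: int = 0, **overrides) -> ArchitectureSpec:
    """Tuned spec for a pattern, with geometry scaled to the image size."""
    pattern = Pattern(pattern)
    g = DEFAULT_GEOMETRY
    s = image_size / 512.0
    kwargs = dict(
        pattern=pattern,
        image_size=image_size,
        n_glands=g["n_glands"].get(pattern, 4),
        gland_radius=(g["gland_radius_mean"] * s, g["gland_radius_sd"] * s),
        nucleus_radius=max(g["nucleus_radius"] * s, 3.0),
        nucleus_peak=g["nucleus_peak"],
        stromal_nuclei_density=(g["single_cell_density"]
                                if pattern is Pattern.SINGLE_CELL
                                else g["stromal_nuclei_density"]),
        background_noise_sd=g["background_noise_sd"],
        lumina=g["cribriform_lumina"],
        seed=seed,
    )
    kwargs.update(overrides)
    return ArchitectureSpec(**kwargs)


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

def _add_nucleus(bumps: np.ndarray, y: float, x: float, sigma: float,
                 amp: float) -> None:
    """Accumulate one truncated Gaussian bump (support radius 2 sigma)."""
    n = bumps.shape[0]
    rad = 2.0 * sigma
    y0, y1 = max(0, int(math.floor(y - rad))), min(n, int(math.ceil(y + rad)) + 1)
    x0, x1 = max(0, int(math.floor(x - rad))), min(n, int(math.ceil(x + rad)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    d2 = yy * yy + xx * xx
    patch = amp * np.exp(-d2 / (2.0 * sigma * sigma))
    patch[d2 > rad * rad] = 0.0
    bumps[y0:y1, x0:x1] += patch


def _place_centers(rng: np.random.Generator, n: int, size: int, margin: float,
                   min_dist: float, max_tries: int = 2000) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centres with a minimum pairwise distance."""
    if 2 * margin >= size and n > 0:
        raise GeometryError("glands do not fit: margin exceeds the frame")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n} glands of minimum distance {min_dist:.1f} "
                f"in a {size}x{size} frame")
        y = rng.uniform(margin, size - margin)
        x = rng.uniform(margin, size - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_dist ** 2 for cy, cx in centers):
            centers.append((y, x))
        tries += 1
    return centers


def _ring(bumps: np.ndarray, rng: np.random.Generator, cy: float, cx: float,
          radius: float, sigma: float, amp: float, n_nuclei: int | None,
          arc: float = 1.0) -> None:
    """A (partial) ring of nuclei around a lumen."""
    spacing = DEFAULT_GEOMETRY["ring_spacing_sigma"] * sigma
    if n_nuclei is None:
        n_nuclei = max(3, int(round(arc * 2 * math.pi * radius / spacing)))
    if n_nuclei == 0:
        return
    phase = rng.uniform(0, 2 * math.pi)
    for i in range(n_nuclei):
        theta = phase + arc * 2 * math.pi * i / max(n_nuclei, 1)
        r = radius + rng.normal(0, 0.02 * radius)
        _add_nucleus(bumps, cy + r * math.sin(theta), cx + r * math.cos(theta),
                     sigma, amp * rng.uniform(0.9, 1.0))


def _sheet(bumps: np.ndarray, rng: np.random.Generator, mask, sigma: float,
           amp: float, size: int) -> None:
    """Tile nuclei on a jittered grid wherever ``mask(y, x)`` holds."""
    spacing = DEFAULT_GEOMETRY["sheet_spacing_sigma"] * sigma
    jitter = 0.15 * spacing
    ny = int(size / spacing) + 2
    for iy in range(ny):
        for ix in range(ny):
            y = (iy + 0.5 * (ix % 2)) * spacing + rng.normal(0, jitter)
            x = ix * spacing + rng.normal(0, jitter)
            if 0 <= y < size and 0 <= x < size and mask(y, x):
                _add_nucleus(bumps, y, x, sigma, amp * rng.uniform(0.9, 1.0))


def generate_roi(spec: ArchitectureSpec) -> np.ndarray:
    """Render one grayscale region of interest in [0, 1] (low = nuclei).

    Deterministic given ``spec.seed``.  Raises :class:`GeometryError` when
    the requested glands cannot be placed without violating the pattern's
    minimum centre distance.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    sigma = spec.nucleus_radius / 2.0
    amp = spec.nucleus_peak
    bumps = np.zeros((size, size))
    gland_centers: list[tuple[float, float, float]] = []  # (y, x, radius)

    p = spec.pattern
    if p in (Pattern.LOOSE_GLANDS, Pattern.CROWDED_GLANDS, Pattern.FUSED,
             Pattern.POORLY_FORMED):
        factor = DEFAULT_GEOMETRY["min_dist_factor"].get(p, 2.0)
        r_mean, r_sd = spec.gland_radius
        if p is Pattern.POORLY_FORMED:
            r_mean, r_sd, factor = 0.5 * r_mean, 0.5 * r_sd, 1.2
        margin = r_mean + 3 * sigma
        centers = _place_centers(rng, spec.n_glands, size, margin,
                                 factor * r_mean)
        for cy, cx in centers:
            radius = max(3 * sigma, rng.normal(r_mean, r_sd))
            arc = rng.uniform(0.4, 0.7) if p is Pattern.POORLY_FORMED else 1.0
            _ring(bumps, rng, cy, cx, radius, sigma, amp,
                  spec.nuclei_per_gland, arc=arc)
            gland_centers.append((cy, cx, radius))
    elif p is Pattern.CRIBRIFORM:
        # one large nuclear mass with punched-out lumina
        mass_r = 0.36 * size
        cy = cx = size / 2.0
        lumen_r = max(0.2 * mass_r, 2.5 * sigma)
        # lumina on a jittered ring inside the mass: always feasible for the
        # supported counts, deterministic given the seed
        reach = mass_r - lumen_r - 2 * sigma
        n_lum = spec.lumina
        if reach <= 0 or 2 * math.sin(math.pi / max(n_lum, 2)) * 0.5 * reach \
                < 2.0 * lumen_r:
            raise GeometryError(
                f"could not place {n_lum} cribriform lumina inside the mass")
        lumina: list[tuple[float, float]] = []
        phase = rng.uniform(0, 2 * math.pi)
        for i in range(n_lum):
            ang = phase + 2 * math.pi * (i + rng.uniform(-0.15, 0.15)) / n_lum
            rad = reach * rng.uniform(0.55, 0.75)
            lumina.append((cy + rad * math.sin(ang), cx + rad * math.cos(ang)))

        def in_mass(y, x):
            if (y - cy) ** 2 + (x - cx) ** 2 > mass_r ** 2:
                return False
            return all((y - ly) ** 2 + (x - lx) ** 2 > lumen_r ** 2
                       for ly, lx in lumina)

        if spec.nuclei_per_gland != 0:
            _sheet(bumps, rng, in_mass, sigma, amp, size)
        gland_centers.append((cy, cx, mass_r))
    elif p is Pattern.SOLID_SHEET:
        if spec.nuclei_per_gland != 0:
            _sheet(bumps, rng, lambda y, x: True, sigma, amp, size)
    elif p is Pattern.SINGLE_CELL:
        pass  # handled by the stromal scatter below, at single-cell density
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown pattern {p}")

    # scattered stromal / infiltrating nuclei (Poisson, isolated)
    density = spec.stromal_nuclei_density
    if p is Pattern.SINGLE_CELL:
        density = max(density, 1e-6)
    n_scatter = rng.poisson(density * size * size) if density > 0 else 0
    min_sep = 2 * (2 * sigma) + 3
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n_scatter and tries < 50 * max(n_scatter, 1):
        y, x = rng.uniform(2 * sigma, size - 2 * sigma, 2)
        tries += 1
        if any((y - py) ** 2 + (x - px) ** 2 < min_sep ** 2 for py, px in placed):
            continue
        if any((y - gy) ** 2 + (x - gx) ** 2 < (gr + 3 * sigma) ** 2
               for gy, gx, gr in gland_centers):
            continue
        placed.append((y, x))
        _add_nucleus(bumps, y, x, sigma, amp)

    image = spec.background - bumps
    if spec.background_noise_sd > 0:
        image = image + rng.normal(0, spec.background_noise_sd, image.shape)
    return np.clip(image, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Pseudo-H&E composition (Beer-Lambert forward model)
# ---------------------------------------------------------------------------

def compose_pseudo_he(hematoxylin_map: np.ndarray, eosin_map: np.ndarray,
                      stain_matrix: StainMatrix | np.ndarray | None = None,
                      i0: float = 255.0) -> np.ndarray:
    """Compose an 8-bit RGB image from stain concentration maps.

    ``RGB = i0 * 10^(-C @ M)`` elementwise, where C stacks the two
    concentration maps and M is the 2x3 unit-row stain matrix.  Inverse of
    the optical-density transform, so deconvolution has an exact target.
    """
    if stain_matrix is None:
        stain_matrix = StainMatrix(CANONICAL_HE)
    elif not isinstance(stain_matrix, StainMatrix):
        stain_matrix = StainMatrix(np.asarray(stain_matrix))
    h = np.asarray(hematoxylin_map, dtype=float)
    e = np.asarray(eosin_map, dtype=float)
    if h.shape != e.shape:
        raise ValueError("concentration maps must share a shape")
    if (h < 0).any() or (e < 0).any():
        raise ValueError("concentrations must be non-negative")
    od = np.stack([h, e], axis=-1) @ stain_matrix.rows
    rgb = i0 * np.power(10.0, -od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def gray_to_concentration(gray: np.ndarray) -> np.ndarray:
    """Map a unit-interval transmission image to stain concentration.

    ``c = -log10(v)`` with v clamped at one intensity level, the exact
    inverse of the transmission rendering used by the deconvolution stage.
    """
    arr = np.asarray(gray, dtype=float)
    return -np.log10(np.clip(arr, 1.0 / 255.0, 1.0))


def pseudo_he_from_gray(gray: np.ndarray, rng: np.random.Generator,
                        stain_matrix: StainMatrix | None = None) -> np.ndarray:
    """Render a grayscale ROI as pseudo-H&E with a smooth eosin background."""
    size = gray.shape[0]
    c_h = gray_to_concentration(gray)
    # smooth low-frequency eosin field (stroma texture), depleted under
    # nuclei where the hematoxylin-stained chromatin displaces cytoplasm
    yy, xx = np.mgrid[0:size, 0:size] / size
    a, b, c = rng.uniform(0.5, 1.5, 3)
    e = 0.25 + 0.1 * np.sin(2 * np.pi * (a * yy + b * xx)) ** 2 + 0.05 * c
    e = e * np.asarray(gray, dtype=float) ** 2
    return compose_pseudo_he(c_h, e, stain_matrix)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def plan_dataset(class_counts: dict[GleasonLabel | str, int],
                 image_size: int = 512, seed: int = 0,
                 patterns: dict | None = None) -> list[ArchitectureSpec]:
    """Plan (without rendering) a labeled collection of ROI specs.

    Patterns cycle round-robin within each class; each spec gets an
    independent child seed derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs: list[ArchitectureSpec] = []
    for label in (GleasonLabel.G3, GleasonLabel.G4, GleasonLabel.G5):
        count = int(class_counts.get(label, class_counts.get(label.value, 0)))
        if count < 0:
            raise ValueError("class counts must be non-negative")
        pats = (patterns or CLASS_PATTERNS)[label]
        for i in range(count):
            child = int(rng.integers(0, 2**31 - 1))
            specs.append(default_spec(pats[i % len(pats)], image_size, seed=child))
    return specs


def generate_dataset(class_counts: dict[GleasonLabel | str, int],
                     image_size: int = 512, seed: int = 0,
                     rgb: bool = False,
                     patterns: dict | None = None) -> list[LabeledImage]:
    """Render a reproducible labeled image collection with exact class counts."""
    specs = plan_dataset(class_counts, image_size, seed, patterns)
    out = []
    for spec in specs:
        img = generate_roi(spec)
        if rgb:
            img = pseudo_he_from_gray(img, np.random.default_rng(spec.seed + 1))
        out.append(LabeledImage(img, PATTERN_GRADE[spec.pattern], spec.pattern, spec))
    return out
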