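"""Stain colour handling: Reinhard normalization and Macenko deconvolution.

Two standard preprocessing steps stand between an H&E RGB image and the
grayscale hematoxylin channel used as a filtration function:

1. **Reinhard colour transfer** — match the per-axis mean and standard
   deviation of the image to those of a reference image in a decorrelated
   colour space.  The original method uses the log-opponent ``lalphabeta``
   space; CIELAB is available as an alternative (``space`` argument).
2. **Macenko colour deconvolution** — convert to optical density (OD),
   where absorbance is linear in stain concentration (Beer-Lambert),
   estimate the two stain OD vectors from the extreme directions of the
   projected OD cloud, and unmix each pixel into hematoxylin and eosin
   concentrations by non-negative least squares.

The hematoxylin concentration is mapped back to an 8-bit transmission image
(high concentration = dark) and rescaled to [0, 1] by the fixed affine map
``v / 255``, preserving the sublevel-set nesting order exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "CANONICAL_HE",
    "ColorStats",
    "StainMatrix",
    "rgb_to_od",
    "od_to_rgb",
    "compute_color_stats",
    "reinhard_normalize",
    "estimate_stain_matrix",
    "deconvolve_hematoxylin",
    "rescale_unit",
    "hematoxylin_channel",
]

# Ruifrok & Johnston's canonical H&E OD vectors (unit rows), a common default.
CANONICAL_HE = np.array([[0.650, 0.704, 0.286],
                         [0.072, 0.990, 0.105]])
CANONICAL_HE /= np.linalg.norm(CANONICAL_HE, axis=1, keepdims=True)

_AXIS_NAMES = {"lalphabeta": ("l", "alpha", "beta"), "cielab": ("L", "a", "b")}

# RGB <-> LMS matrices of the log-opponent colour-transfer method.
_RGB2LMS = np.array([[0.3811, 0.5783, 0.0402],
                     [0.1967, 0.7244, 0.0782],
                     [0.0241, 0.1288, 0.8444]])
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LMS2LAB = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float)
_LAB2LMS = np.linalg.inv(_LMS2LAB)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return image


# ---------------------------------------------------------------------------
# Optical density
# ---------------------------------------------------------------------------

def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Optical density ``-log10(I / i0)`` per channel.

    Intensities are clamped below at one intensity level so that a zero
    pixel maps to a finite OD; ``I = i0`` maps to OD 0 exactly.
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    arr = np.asarray(image, dtype=float)
    return -np.log10(np.clip(arr, 1.0, i0) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (8-bit, rounded)."""
    arr = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def rescale_unit(gray: np.ndarray) -> np.ndarray:
    """Fixed affine rescale from [0, 255] to [0, 1] (``v / 255``).

    Deliberately *not* a per-image min-max stretch: the map is the same for
    every image, so sublevel-set nesting and cross-image comparability are
    preserved.
    """
    arr = np.asarray(gray, dtype=float)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("input values must lie in [0, 255]")
    return arr / 255.0


# ---------------------------------------------------------------------------
# Reinhard colour transfer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorStats:
    """Per-axis mean and standard deviation in a normalization colour space."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    space: str = "lalphabeta"

    def __post_init__(self) -> None:
        if self.space not in _AXIS_NAMES:
            raise ValueError(f"unknown colour space {self.space!r}")
        if any(sd <= 0 for sd in self.sds):
            raise ValueError("standard deviations must be positive")


def _to_space(image: np.ndarray, space: str) -> np.ndarray:
    rgb = _check_rgb(image).astype(float) / 255.0
    if space == "cielab":
        return _skcolor.rgb2lab(rgb)
    # log-opponent lalphabeta
    lms = rgb @ _RGB2LMS.T
    lms = np.log10(np.clip(lms, 1e-6, None))
    return lms @ _LMS2LAB.T


def _from_space(arr: np.ndarray, space: str) -> np.ndarray:
    if space == "cielab":
        rgb = _skcolor.lab2rgb(arr)
    else:
        lms = np.power(10.0, arr @ _LAB2LMS.T)
        rgb = lms @ _LMS2RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def compute_color_stats(image: np.ndarray, space: str = "lalphabeta") -> ColorStats:
    """Mean/SD per axis of ``image`` in the chosen normalization space."""
    arr = _to_space(image, space)
    means = arr.reshape(-1, 3).mean(axis=0)
    sds = arr.reshape(-1, 3).std(axis=0)
    return ColorStats(tuple(means), tuple(np.maximum(sds, 0.0)), space)


def reinhard_normalize(target: np.ndarray, source_stats: ColorStats) -> np.ndarray:
    """Transfer the colour statistics of a source image onto ``target``.

    Per axis x of the normalization space:
    ``x <- (x - mean_target) * (sd_source / sd_target) + mean_source``.

    Raises if the target is constant along any axis (sd = 0), naming the
    offending axis.
    """
    space = source_stats.space
    arr = _to_space(target, space)
    flat = arr.reshape(-1, 3)
    t_means = flat.mean(axis=0)
    t_sds = flat.std(axis=0)
    for i, sd in enumerate(t_sds):
        if sd <= 1e-8:  # constant up to floating-point rounding
            raise ValueError(
                f"target image is constant along axis {_AXIS_NAMES[space][i]!r}; "
                "cannot normalize")
    out = (arr - t_means) * (np.asarray(source_stats.sds) / t_sds) + np.asarray(
        source_stats.means)
    return _from_space(out, space)


# ---------------------------------------------------------------------------
# Macenko stain estimation and unmixing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainMatrix:
    """Two unit OD row vectors: hematoxylin first, eosin second."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (2, 3):
            raise ValueError("stain matrix must be 2x3")
        if (rows < -1e-9).any():
            raise ValueError("stain OD components must be non-negative")
        norms = np.linalg.norm(rows, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain rows must have unit Euclidean norm")
        if np.linalg.matrix_rank(rows, tol=1e-8) < 2:
            raise ValueError("stain rows are collinear")
        object.__setattr__(self, "rows", rows)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.rows[0]

    @property
    def eosin(self) -> np.ndarray:
        return self.rows[1]


def estimate_stain_matrix(od: np.ndarray, alpha: float = 1.0,
                          beta: float = 0.15) -> StainMatrix:
    """Estimate H&E stain vectors from an OD image (Macenko's procedure).

    Pixels of OD magnitude below ``beta`` (background) are discarded; the
    remaining OD vectors are projected onto the plane of the top two
    singular directions; the stain vectors are the directions at the
    ``alpha``-th and ``(100 - alpha)``-th percentiles of the angular
    distribution.  The hematoxylin row is the one with the larger
    blue-channel OD component.
    """
    pts = np.asarray(od, dtype=float).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) > beta]
    if len(pts) < 10:
        raise ValueError("insufficient stained tissue (fewer than 10 pixels above "
                         f"OD threshold {beta})")
    # lexicographic sort makes the Gram matrix (and hence the estimate)
    # exactly invariant to pixel order
    pts = pts[np.lexsort(pts.T[::-1])]
    gram = pts.T @ pts
    evals, evecs = np.linalg.eigh(gram)
    if evals[-2] <= 1e-10 * max(evals[-1], 1.0):
        raise ValueError("degenerate stain distribution: angular spread is zero "
                         "(single stain?)")
    v1, v2 = evecs[:, -1], evecs[:, -2]
    # fix signs so projections onto v1 are mostly positive (OD is non-negative)
    if (pts @ v1).sum() < 0:
        v1 = -v1
    if (pts @ v2).sum() < 0:
        v2 = -v2
    phi = np.arctan2(pts @ v2, pts @ v1)
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    if hi - lo < 1e-6:
        raise ValueError("degenerate stain distribution: angular spread is zero "
                         "(single stain?)")
    s1 = np.cos(lo) * v1 + np.sin(lo) * v2
    s2 = np.cos(hi) * v1 + np.sin(hi) * v2
    rows = np.stack([s1, s2])
    rows = np.clip(rows, 0.0, None)
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    # hematoxylin is blue-purple: larger blue OD component
    if rows[0, 2] < rows[1, 2]:
        rows = rows[::-1]
    return StainMatrix(rows)


def _nnls_two_stains(od_flat: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Vectorized NNLS for the 2-stain unmixing problem.

    For two variables the active sets can be enumerated: the unconstrained
    normal-equation solution if feasible, otherwise the better of the two
    single-stain fits (clipped at zero).
    """
    g = m @ m.T                    # 2x2
    b = od_flat @ m.T              # (N, 2)
    det = g[0, 0] * g[1, 1] - g[0, 1] * g[1, 0]
    c1 = (g[1, 1] * b[:, 0] - g[0, 1] * b[:, 1]) / det
    c2 = (g[0, 0] * b[:, 1] - g[1, 0] * b[:, 0]) / det
    free = np.stack([c1, c2], axis=1)
    # single-stain candidates
    cand1 = np.stack([np.clip(b[:, 0] / g[0, 0], 0, None),
                      np.zeros(len(b))], axis=1)
    cand2 = np.stack([np.zeros(len(b)),
                      np.clip(b[:, 1] / g[1, 1], 0, None)], axis=1)

    def q(c):  # objective up to a constant: c'Gc - 2 b.c
        return np.einsum("ni,ij,nj->n", c, g, c) - 2 * np.einsum("ni,ni->n", c, b)

    out = np.where((free >= 0).all(axis=1)[:, None], free,
                   np.where((q(cand1) <= q(cand2))[:, None], cand1, cand2))
    return out


def deconvolve_hematoxylin(image: np.ndarray, m: StainMatrix,
                           i0: float = 255.0) -> np.ndarray:
    """Hematoxylin channel of an RGB image as a unit-interval grayscale image.

    Per pixel, the OD vector is decomposed as ``c_H * m_H + c_E * m_E``
    with non-negative concentrations; ``c_H`` is rendered back to an 8-bit
    transmission image (``255 * 10^-c_H``, dark = concentrated) and rescaled
    to [0, 1].
    """
    od = rgb_to_od(image, i0=i0)
    conc = _nnls_two_stains(od.reshape(-1, 3), m.rows)
    c_h = conc[:, 0].reshape(od.shape[:2])
    gray = np.clip(np.rint(255.0 * np.power(10.0, -c_h)), 0, 255)
    return rescale_unit(gray)


def hematoxylin_channel(image: np.ndarray, alpha: float = 1.0, beta: float = 0.15,
                        source_stats: ColorStats | None = None) -> np.ndarray:
    """Full preprocessing: optional Reinhard transfer, then Macenko unmixing.

    The stain matrix is estimated per image; falls back to the canonical
    H&E matrix when estimation is degenerate (e.g. a nearly single-stain
    field).
    """
    if source_stats is not None:
        image = reinhard_normalize(image, source_stats)
    od = rgb_to_od(image)
    try:
        m = estimate_stain_matrix(od, alpha=alpha, beta=beta)
    except ValueError:
        warnings.warn("stain estimation degenerate; using canonical H&E matrix",
                      stacklevel=2)
        m = StainMatrix(CANONICAL_HE)
    return deconvolve_hematoxylin(image, m)
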