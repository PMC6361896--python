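"""Vector and surface representations of persistence diagrams.

Two representations feed the downstream clustering:

* **Ranked persistence vectors** — per image, the persistences
  ``|death - birth|`` of the H0 and H1 points, each list sorted in
  descending order, truncated to the minimum H0 / H1 feature counts across
  the image collection, and concatenated (H0 part first).  Truncation to
  the collection-wide minima makes vectors of a common length without
  padding, at the cost of dropping the shortest-lived features of richer
  images.

* **Persistence intensity diagrams** — a kernel density surface over the
  (birth, death) plane where each diagram point contributes a Gaussian
  bump weighted by its persistence:

      K_hat(x, y) = sum_i (d_i - b_i) * (1/s^2) * K((x-b_i)/s) * K((y-d_i)/s)

  with K the standard Gaussian density and smoothing parameter ``s``
  (default 0.05, minimal smoothing at unit-interval scale).  Surfaces are
  computed separately for dimension 0 and 1, and essential classes enter
  at their recorded death of 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .persistence import PersistenceDiagram

__all__ = [
    "IntensityDiagram",
    "rank_persistence",
    "truncate_and_concat",
    "intensity_diagram",
    "average_intensity",
]

DEFAULT_SIGMA_SMOOTH = 0.05
DEFAULT_RESOLUTION = 128


def rank_persistence(diagram: PersistenceDiagram, dim: int) -> np.ndarray:
    """Persistences of dimension-``dim`` points, sorted non-increasing."""
    pers = diagram.persistences(dim)
    return np.sort(pers)[::-1].copy()


def truncate_and_concat(
    diagrams: Sequence[PersistenceDiagram],
) -> tuple[np.ndarray, int, int]:
    """Build the ranked-persistence feature matrix for one image collection.

    Returns ``(matrix, n0, n1)`` where ``matrix`` has one row per image of
    length ``n0 + n1``; ``n0``/``n1`` are the minimum H0/H1 point counts
    across the collection.  If any image has no H1 points the H1 part is
    empty (a warning is emitted).
    """
    if len(diagrams) == 0:
        raise ValueError("need at least one diagram")
    h0 = [rank_persistence(d, 0) for d in diagrams]
    h1 = [rank_persistence(d, 1) for d in diagrams]
    if any(len(v) == 0 for v in h0):
        raise ValueError("every image must have at least one H0 point")
    n0 = min(len(v) for v in h0)
    n1 = min(len(v) for v in h1)
    if n1 == 0:
        warnings.warn("an image has no H1 features; H1 part of the ranked "
                      "vectors is empty", stacklevel=2)
    rows = [np.concatenate([a[:n0], b[:n1]]) for a, b in zip(h0, h1)]
    return np.vstack(rows), n0, n1


@dataclass(frozen=True)
class IntensityDiagram:
    """Discretised persistence-intensity surface over the (birth, death) plane."""

    values: np.ndarray          # (res_x, res_y); [i, j] = K_hat(x_i, y_j)
    xs: np.ndarray              # birth-axis evaluation points
    ys: np.ndarray              # death-axis evaluation points
    sigma_smooth: float
    dim: int

    def __post_init__(self) -> None:
        if (self.values < 0).any() or not np.isfinite(self.values).all():
            raise ValueError("intensity values must be finite and non-negative")

    def integral(self) -> float:
        """Trapezoidal integral of the surface over its grid."""
        return float(np.trapezoid(np.trapezoid(self.values, self.ys, axis=1),
                                  self.xs))


def intensity_diagram(diagram: PersistenceDiagram, dim: int,
                      sigma_smooth: float = DEFAULT_SIGMA_SMOOTH,
                      resolution: int = DEFAULT_RESOLUTION,
                      extent: tuple[float, float] = (0.0, 1.0)) -> IntensityDiagram:
    """Persistence-weighted Gaussian intensity surface for one dimension.

    Evaluated on a regular ``resolution`` x ``resolution`` grid over
    ``extent`` squared (default the unit square; pass a wider extent to
    capture kernel mass spilling past the boundary).
    """
    if sigma_smooth <= 0:
        raise ValueError("sigma_smooth must be positive")
    xs = np.linspace(extent[0], extent[1], resolution)
    ys = xs.copy()
    pts = diagram.points(dim)
    if len(pts) == 0:
        values = np.zeros((resolution, resolution))
    else:
        w = np.abs(pts[:, 1] - pts[:, 0])
        gx = norm.pdf((xs[None, :] - pts[:, 0:1]) / sigma_smooth)   # (n, res)
        gy = norm.pdf((ys[None, :] - pts[:, 1:2]) / sigma_smooth)
        values = (w[:, None] * gx).T @ gy / sigma_smooth**2
    return IntensityDiagram(values, xs, ys, sigma_smooth, dim)


def average_intensity(diagrams: Sequence[IntensityDiagram],
                      membership: Sequence[int],
                      clusters: Sequence[int] | None = None,
                      ) -> dict[int, IntensityDiagram]:
    """Pointwise mean intensity surface per cluster.

    ``membership[i]`` assigns ``diagrams[i]`` to a cluster.  ``clusters``
    optionally names the expected cluster labels; a named cluster with no
    members raises an error identifying it.
    """
    membership = np.asarray(membership)
    if len(membership) != len(diagrams):
        raise ValueError("membership must assign every diagram")
    if clusters is None:
        clusters = np.unique(membership)
    ref = diagrams[0]
    out: dict[int, IntensityDiagram] = {}
    for label in clusters:
        if not (membership == label).any():
            raise ValueError(f"cluster {label} is empty")
        members = [d for d, m in zip(diagrams, membership) if m == label]
        if any(d.values.shape != ref.values.shape or d.dim != members[0].dim
               for d in members):
            raise ValueError("member surfaces must share grid and dimension")
        mean = np.mean([d.values for d in members], axis=0)
        out[int(label)] = IntensityDiagram(mean, members[0].xs, members[0].ys,
                                           members[0].sigma_smooth,
                                           members[0].dim)
    return out
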