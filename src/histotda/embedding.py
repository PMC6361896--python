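"""t-SNE visualization with information-criterion perplexity selection.

t-SNE maps the PCA scores of one bootstrap to two dimensions by matching
neighbourhood distributions; its single load-bearing free parameter, the
perplexity ``p`` (the effective neighbour count), is chosen automatically
by a pseudo Bayesian information criterion that trades off the converged
KL divergence against model complexity:

    pBIC(p) = 2 KL(P || Q) + log(n) * p / n

with n the number of embedded points.  The natural logarithm is used, the
convention of the BIC; base 10 is available via ``log_base``.  The scan
averages pBIC over bootstraps and picks the argmin within a selection
window (default perplexities 5 to 50), ties going to the smallest p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.manifold import TSNE

__all__ = ["EmbeddingResult", "tsne_embed", "pbic", "select_perplexity"]


@dataclass(frozen=True)
class EmbeddingResult:
    """A 2-D embedding with its convergence and criterion values."""

    coords: np.ndarray       # (n, 2)
    perplexity: float
    kl: float                # converged KL(P||Q)
    n: int
    pbic: float


def pbic(kl: float, p: float, n: int, log_base: str = "e") -> float:
    """``2 * KL + log(n) * p / n``; the complexity term uses log base ``log_base``."""
    if kl < 0 or not math.isfinite(kl):
        raise ValueError("KL divergence must be finite and non-negative")
    if not (1 <= p < n):
        raise ValueError("perplexity must satisfy 1 <= p < n")
    log = math.log if log_base == "e" else math.log10
    return 2.0 * kl + log(n) * p / n


def tsne_embed(scores: np.ndarray, p: float, seed: int | None = None,
               log_base: str = "e") -> EmbeddingResult:
    """Seeded 2-D t-SNE of ``scores`` at perplexity ``p``."""
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if not (1 <= p < n):
        raise ValueError("perplexity must satisfy 1 <= p < n")
    tsne = TSNE(n_components=2, perplexity=p, random_state=seed, init="pca")
    coords = tsne.fit_transform(x)
    kl = float(tsne.kl_divergence_)
    return EmbeddingResult(coords, float(p), kl, n, pbic(kl, p, n, log_base))


def select_perplexity(scores_per_bootstrap: Sequence[np.ndarray],
                      p_range: Sequence[float],
                      selection_window: tuple[float, float] = (5.0, 50.0),
                      seed: int | None = None,
                      log_base: str = "e") -> tuple[float, np.ndarray]:
    """Scan perplexities, average pBIC over bootstraps, pick the window argmin.

    Returns ``(chosen_p, curve)`` where ``curve`` is a (len(p_range), 2)
    array of (p, mean pBIC).  Ties break toward the smallest p.
    """
    ps = sorted(p_range)
    if not ps:
        raise ValueError("p_range must be non-empty")
    lo, hi = selection_window
    if not any(lo <= p <= hi for p in ps):
        raise ValueError("selection window contains no scanned perplexity")
    curve = np.empty((len(ps), 2))
    for i, p in enumerate(ps):
        vals = [tsne_embed(s, p, seed=seed, log_base=log_base).pbic
                for s in scores_per_bootstrap]
        curve[i] = (p, float(np.mean(vals)))
    in_window = [(pb, p) for p, pb in curve if lo <= p <= hi]
    chosen = min(in_window)[1]
    return float(chosen), curve


# ---------------------------------------------------------------------------
# Figure assembly
# ---------------------------------------------------------------------------

#: Marker per Gleason label in the embedding scatter.
LABEL_MARKERS = {"G3": "o", "G4": "^", "G5": "s"}


def render_figure(embedding: EmbeddingResult, assignment: Sequence[int],
                  labels: Sequence[str], compositions: np.ndarray,
                  intensity_panels: Sequence | None, outdir,
                  fmt: str = "svg") -> list:
    """Write the discovery figures: scatter, composition bars, intensity panels.

    The scatter colours points by cluster and shapes them by Gleason label;
    each cluster gets a composition bar chart with standard-error bars;
    intensity panels (pairs of dim-0 / dim-1 surfaces per cluster) are
    rendered as image grids.  Rendering is deterministic: a fixed SVG hash
    salt and no embedded timestamps, so identical inputs give identical
    bytes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if len(assignment) != len(embedding.coords) or len(labels) != len(assignment):
        raise ValueError("embedding, assignment and labels must align")
    clusters = np.unique(assignment)
    if len(clusters) == 0:
        raise ValueError("empty cluster set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matplotlib.rcParams["svg.hashsalt"] = "histotda"
    meta = {"Date": None} if fmt == "svg" else {}
    written = []

    cmap = matplotlib.colormaps["tab10"]
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in clusters:
        for lab, marker in LABEL_MARKERS.items():
            sel = (assignment == c) & (labels == lab)
            if sel.any():
                ax.scatter(embedding.coords[sel, 0], embedding.coords[sel, 1],
                           s=14, marker=marker, color=cmap((c - 1) % 10),
                           label=f"cluster {c} / {lab}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(f"perplexity {embedding.perplexity:g}, KL {embedding.kl:.3f}")
    path = outdir / f"embedding.{fmt}"
    fig.savefig(path, metadata=meta)
    plt.close(fig)
    written.append(path)

    comp = np.asarray(compositions, dtype=float)
    for j, c in enumerate(clusters):
        fig, ax = plt.subplots(figsize=(3, 3))
        vals = comp[j]
        total = vals.sum()
        frac = vals / total if total > 0 else vals
        se = np.sqrt(np.clip(frac * (1 - frac), 0, None) / max(total, 1))
        ax.bar(["G3", "G4", "G5"], frac, yerr=se, capsize=3,
               color=cmap((c - 1) % 10))
        ax.set_ylim(0, 1)
        ax.set_title(f"cluster {c} composition")
        path = outdir / f"composition_cluster{c}.{fmt}"
        fig.savefig(path, metadata=meta)
        plt.close(fig)
        written.append(path)

    for j, panel in enumerate(intensity_panels or []):
        for d, surface in enumerate(panel):
            fig, ax = plt.subplots(figsize=(3, 3))
            ax.imshow(surface.values.T, origin="lower", cmap="viridis",
                      extent=(surface.xs[0], surface.xs[-1],
                              surface.ys[0], surface.ys[-1]))
            ax.set_xlabel("birth")
            ax.set_ylabel("death")
            ax.set_title(f"cluster {clusters[j]} H{surface.dim}")
            path = outdir / f"intensity_cluster{clusters[j]}_dim{surface.dim}.{fmt}"
            fig.savefig(path, metadata=meta)
            plt.close(fig)
            written.append(path)
    return written
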