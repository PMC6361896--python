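"""End-to-end orchestration of the discovery pipeline.

Ties the stages together for a collection of labeled grayscale images:
persistence diagrams -> per-bootstrap ranked vectors -> PCA -> Ward ->
composition vectors -> meta-clustering -> representative bootstrap ->
Jaccard stability.  Each stage remains individually usable; this module
only sequences them and carries bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import discovery
from .features import truncate_and_concat
from .persistence import PersistenceDiagram, compute_persistence

__all__ = ["DiscoveryResult", "diagrams_for_images", "run_discovery"]


def diagrams_for_images(images: Sequence[np.ndarray]) -> list[PersistenceDiagram]:
    """Sublevel-set persistence diagram of every image."""
    return [compute_persistence(img) for img in images]


@dataclass
class DiscoveryResult:
    """Everything the discovery chain produces, per bootstrap and pooled."""

    bootstraps: list                      # BootstrapSample per bootstrap
    assignments: list[np.ndarray]         # per-bootstrap cluster ids (1..k)
    acs: np.ndarray                       # agglomerative coefficient per bootstrap
    feature_shapes: list[tuple[int, int]]  # (n0, n1) ranked-vector parts
    scores: list[np.ndarray]              # per-bootstrap PCA scores
    meta: discovery.MetaClusterResult
    representative: int
    jaccard: np.ndarray                   # per-meta-cluster mean Jaccard


def run_discovery(diagrams: Sequence[PersistenceDiagram], labels: Sequence[str],
                  n_bootstraps: int = 100, k: int | None = None,
                  k_range: Sequence[int] = range(2, 11),
                  n_components: int = 6, gap_b: int = 100,
                  gap_scan_bootstraps: int = 5, n_jaccard: int = 1000,
                  seed: int | None = None) -> DiscoveryResult:
    """Run the full unsupervised chain on per-image diagrams and grade labels.

    ``k`` fixes the within-bootstrap cluster count; when None, it is chosen
    by the maximum of the mean Gap curve over ``k_range``, averaged across
    the first ``gap_scan_bootstraps`` bootstraps (scanning every bootstrap
    is redundant: the balanced subsamples are exchangeable).  The
    meta-level cluster count is then chosen independently by the Gap
    one-standard-error rule over 1..max(k_range).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    boots = discovery.balanced_bootstrap(labels, n_bootstraps,
                                         seed=int(rng.integers(2**31 - 1)))
    matrices, shapes, scores_list = [], [], []
    for bs in boots:
        idx = bs.all_indices
        matrix, n0, n1 = truncate_and_concat([diagrams[i] for i in idx])
        scores, _ = discovery.pca_project(matrix,
                                          min(n_components, matrix.shape[1]))
        matrices.append(matrix)
        shapes.append((n0, n1))
        scores_list.append(scores)

    if k is None:
        curves = []
        for scores in scores_list[:max(1, gap_scan_bootstraps)]:
            g = discovery.gap_statistic(scores, k_range, b_ref=gap_b,
                                        rule="max_mean",
                                        seed=int(rng.integers(2**31 - 1)))
            curves.append(g.gap)
        per_boot_k = int(np.asarray(sorted(k_range))[
            np.argmax(np.mean(curves, axis=0))])
    else:
        per_boot_k = k

    assignments, acs, vectors, boot_ids = [], [], [], []
    for bs, scores in zip(boots, scores_list):
        idx = bs.all_indices
        assign = discovery.ward_cluster(scores, per_boot_k)
        comp = discovery.composition_vector(assign, labels[idx])
        assignments.append(assign.labels)
        acs.append(assign.ac)
        vectors.append(comp)
        boot_ids.extend([bs.bootstrap_id] * len(comp))
    pooled = np.vstack(vectors)
    meta_range = [kk for kk in range(1, max(k_range) + 1)]
    meta = discovery.meta_cluster(pooled, boot_ids, k=k, k_range=meta_range,
                                  b_ref=gap_b,
                                  seed=int(rng.integers(2**31 - 1)))
    rep = discovery.representative_bootstrap(meta)
    jac = discovery.jaccard_stability(meta, n_resamples=n_jaccard,
                                      seed=int(rng.integers(2**31 - 1)))
    return DiscoveryResult(boots, assignments, np.asarray(acs), shapes,
                           scores_list, meta, rep, jac)
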