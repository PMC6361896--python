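"""Sublevel-set persistence: worked examples, oracle equivalence, invariances."""

import networkx as nx
import numpy as np
import pytest

from histotda.persistence import (PersistenceDiagram, brute_force_persistence,
                                  build_lower_star_filtration,
                                  compute_persistence)

from conftest import random_quantized_image


def bottleneck_leq(d1: PersistenceDiagram, d2: PersistenceDiagram,
                   delta: float) -> bool:
    """Feasibility check: does a matching of max L-inf cost <= delta exist?

    Points may match across diagrams (cost = L-inf distance) or to the
    diagonal (cost = persistence / 2).  Implemented as bipartite maximum
    matching on the <=delta edges; independent of the persistence code.
    """
    for dim in (0, 1):
        a = d1.points(dim)
        b = d2.points(dim)
        # left: a-points and a diagonal copy per b-point; right: b-points and
        # a diagonal copy per a-point; bottleneck <= delta iff a perfect
        # matching of size |A| + |B| exists.
        left = [("a", i) for i in range(len(a))] + [("db", j) for j in range(len(b))]
        g = nx.Graph()
        g.add_nodes_from(("L", node) for node in left)
        g.add_nodes_from(("R", ("b", j)) for j in range(len(b)))
        g.add_nodes_from(("R", ("da", i)) for i in range(len(a)))
        for i, p in enumerate(a):
            for j, q in enumerate(b):
                if np.abs(p - q).max() <= delta:
                    g.add_edge(("L", ("a", i)), ("R", ("b", j)))
            if (p[1] - p[0]) / 2 <= delta:
                g.add_edge(("L", ("a", i)), ("R", ("da", i)))
        for j, q in enumerate(b):
            if (q[1] - q[0]) / 2 <= delta:
                g.add_edge(("L", ("db", j)), ("R", ("b", j)))
            for i in range(len(a)):
                g.add_edge(("L", ("db", j)), ("R", ("da", i)))
        if len(a) + len(b) == 0:
            continue
        match = nx.bipartite.maximum_matching(
            g, top_nodes=[("L", node) for node in left])
        if len(match) // 2 < len(a) + len(b):
            return False
    return True


class TestFiltration:
    def test_single_pixel(self):
        cells = build_lower_star_filtration(np.array([[0.5]]))
        assert [c[1] for c in cells] == [0]

    def test_two_by_two_counts(self):
        cells = build_lower_star_filtration(np.zeros((2, 2)))
        dims = [c[1] for c in cells]
        assert dims.count(0) == 4 and dims.count(1) == 5 and dims.count(2) == 2

    @pytest.mark.parametrize("shape", [(1, 7), (3, 4), (5, 5), (2, 9)])
    def test_euler_characteristic_of_disk(self, shape):
        cells = build_lower_star_filtration(np.zeros(shape))
        dims = np.array([c[1] for c in cells])
        v, e, t = (dims == 0).sum(), (dims == 1).sum(), (dims == 2).sum()
        assert v - e + t == 1

    def test_faces_precede_cofaces(self, rng):
        img = random_quantized_image(rng)
        cells = build_lower_star_filtration(img)
        pos = {(dim, idx): j for j, (_, dim, idx, _) in enumerate(cells)}
        for j, (_, dim, _, faces) in enumerate(cells):
            assert all(pos[(dim - 1, f)] < j for f in faces)


class TestComputePersistence:
    def test_constant_image(self):
        d = compute_persistence(np.full((6, 6), 0.3))
        assert d.as_multiset() == [(0, 0.3, 1.0)]
        assert d.essential.sum() == 1

    def test_dark_ring(self, ring_image):
        d = compute_persistence(ring_image)
        h1 = d.points(1)
        assert len(h1) == 1
        assert h1[0] == pytest.approx([0.1, 0.9])

    def test_matches_oracle_on_ring(self, ring_image):
        assert (compute_persistence(ring_image).as_multiset()
                == brute_force_persistence(ring_image).as_multiset())

    def test_rejects_non_finite(self):
        img = np.ones((3, 3))
        img[1, 1] = np.nan
        with pytest.raises(ValueError):
            compute_persistence(img)

    def test_betti_numbers_at_top(self, rng):
        # a full rectangle is contractible: one component, no loops survive
        d = compute_persistence(rng.random((10, 10)))
        assert d.essential.sum() == 1
        assert int(d.dims[d.essential][0]) == 0
        assert (d.deaths[~d.essential] <= 1.0).all()

    def test_monotone_relabeling_equivariance(self, rng):
        img = random_quantized_image(rng)
        g = lambda v: v**2 + 0.1 * v  # strictly increasing on [0, 1]
        d1 = compute_persistence(img)
        d2 = compute_persistence(g(img))
        # essential death stays pinned at 1.0; compare non-essential pairs
        m1 = sorted((k, g(b), g(dd)) for k, b, dd, e in
                    zip(d1.dims, d1.births, d1.deaths, d1.essential) if not e)
        m2 = sorted((k, b, dd) for k, b, dd, e in
                    zip(d2.dims, d2.births, d2.deaths, d2.essential) if not e)
        assert np.allclose(np.array(m1), np.array(m2))

    def test_constant_shift_equivariance(self, rng):
        img = 0.2 + 0.5 * rng.random((8, 8))
        shift = 0.1
        d1 = compute_persistence(img)
        d2 = compute_persistence(img + shift)
        m1 = sorted((k, b + shift, dd + shift) for k, b, dd, e in
                    zip(d1.dims, d1.births, d1.deaths, d1.essential) if not e)
        m2 = sorted((k, b, dd) for k, b, dd, e in
                    zip(d2.dims, d2.births, d2.deaths, d2.essential) if not e)
        assert np.allclose(np.array(m1), np.array(m2))

    @pytest.mark.parametrize("delta", [0.01, 0.05])
    def test_stability_under_perturbation(self, rng, delta):
        img = rng.random((12, 12))
        noise = rng.uniform(-delta, delta, img.shape)
        pert = np.clip(img + noise, 0, 1)
        d1 = compute_persistence(img)
        d2 = compute_persistence(pert)
        assert bottleneck_leq(d1, d2, delta + 1e-12)


class TestBruteForce:
    def test_refuses_large_images(self):
        with pytest.raises(ValueError, match="16x16"):
            brute_force_persistence(np.zeros((17, 5)))

    def test_constant_image(self):
        d = brute_force_persistence(np.full((4, 4), 0.7))
        assert d.as_multiset() == [(0, 0.7, 1.0)]

    def test_oracle_equivalence_small_battery(self, rng):
        for _ in range(40):
            img = random_quantized_image(rng, max_side=8)
            assert (compute_persistence(img).as_multiset()
                    == brute_force_persistence(img).as_multiset())

    def test_oracle_equivalence_degenerate_shapes(self):
        for img in (np.zeros((1, 1)), np.linspace(0, 1, 9).reshape(1, 9),
                    np.linspace(0, 1, 9).reshape(9, 1)):
            assert (compute_persistence(img).as_multiset()
                    == brute_force_persistence(img).as_multiset())


class TestDiagramContainer:
    def test_birth_must_not_exceed_death(self):
        with pytest.raises(ValueError):
            PersistenceDiagram(np.array([0]), np.array([0.5]), np.array([0.2]))

    def test_points_and_persistences(self):
        d = PersistenceDiagram(np.array([0, 1]), np.array([0.1, 0.2]),
                               np.array([1.0, 0.6]), np.array([True, False]))
        assert d.points(1).tolist() == [[0.2, 0.6]]
        assert d.persistences(1) == pytest.approx([0.4])
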