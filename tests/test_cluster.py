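"""Electrode adjacency and cluster-mass permutation tests."""

import numpy as np
import pytest

from freqtag.cluster import (
    DegenerateLayoutError,
    build_adjacency,
    cluster_mass_test,
)
from freqtag.design import InvalidParameterError


@pytest.fixture(scope="module")
def adjacency32(layout32_module):
    return build_adjacency(layout32_module)


@pytest.fixture(scope="module")
def layout32_module():
    from freqtag.layout import make_layout

    return make_layout(32, np.random.default_rng(0))


def contiguous_patch(adjacency, start, size):
    """A connected set of ``size`` electrodes grown from ``start``."""
    nbrs = adjacency.neighbour_lists()
    patch = [start]
    frontier = list(nbrs[start])
    while len(patch) < size and frontier:
        nxt = frontier.pop(0)
        if nxt not in patch:
            patch.append(nxt)
            frontier += [n for n in nbrs[nxt] if n not in patch]
    return np.array(sorted(patch[:size]))


class TestAdjacency:
    def test_unit_square_triangulation(self):
        """Hand triangulation of the unit square: 4 sides + 1 diagonal."""
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        graph = build_adjacency(pos)
        assert graph.n_nodes == 4
        assert len(graph.edges) == 5

    def test_matrix_symmetric_no_self_edges(self, adjacency32):
        m = adjacency32.matrix
        np.testing.assert_array_equal(m, m.T)
        assert not m.diagonal().any()

    def test_default_montage_well_connected(self, layout125):
        graph = build_adjacency(layout125)
        assert graph.n_nodes == 125
        assert graph.degree().min() >= 2

    def test_degenerate_layouts_rejected(self):
        with pytest.raises(DegenerateLayoutError):
            build_adjacency(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with pytest.raises(DegenerateLayoutError):
            build_adjacency(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))


class TestClusterMass:
    def test_identical_inputs_give_no_clusters(self, adjacency32, rng):
        a = rng.standard_normal((12, 32))
        res = cluster_mass_test(a, a.copy(), adjacency32, design="paired",
                                n_perm=100, rng=rng)
        assert res.clusters == []

    def test_small_patch_blocked_by_min_size(self, adjacency32, rng):
        """A strong effect on only 2 adjacent electrodes never forms a
        reportable cluster at min_size=4."""
        i, j = adjacency32.edges[0]
        a = rng.standard_normal((15, 32))
        b = rng.standard_normal((15, 32))
        a[:, [i, j]] += 5.0
        res = cluster_mass_test(a, b, adjacency32, design="paired",
                                min_size=4, n_perm=100, rng=rng)
        assert all(set(c.electrodes) - {i, j} for c in res.clusters)
        res1 = cluster_mass_test(a, b, adjacency32, design="paired",
                                 min_size=1, n_perm=100,
                                 rng=np.random.default_rng(0))
        assert any({i, j} <= set(c.electrodes) for c in res1.clusters)

    def test_recovers_contiguous_injected_effect(self, adjacency32):
        """10-electrode injected patch found (>= half overlap) in >=90% of
        seeded paired one-tailed runs."""
        patch = contiguous_patch(adjacency32, 5, 10)
        hits = 0
        n_runs = 12
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((20, 32))
            b = rng.standard_normal((20, 32))
            a[:, patch] += 1.2
            res = cluster_mass_test(a, b, adjacency32, design="paired",
                                    tail="one", alpha=0.05, n_perm=200, rng=rng)
            sig = res.significant()
            if sig and max(
                len(set(c.electrodes) & set(patch)) for c in sig
            ) >= len(patch) / 2:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_two_tailed_sign_flip_invariance(self, adjacency32, rng):
        a = rng.standard_normal((14, 32))
        b = rng.standard_normal((14, 32))
        a[:, :8] += 1.0
        res_pos = cluster_mass_test(a, b, adjacency32, design="paired", tail="two",
                                    alpha=0.025, n_perm=150,
                                    rng=np.random.default_rng(9))
        res_neg = cluster_mass_test(-a, -b, adjacency32, design="paired", tail="two",
                                    alpha=0.025, n_perm=150,
                                    rng=np.random.default_rng(9))
        assert len(res_pos.clusters) == len(res_neg.clusters)
        for cp, cn in zip(res_pos.clusters, res_neg.clusters):
            assert cp.electrodes == cn.electrodes
            assert cp.mass == pytest.approx(-cn.mass)
            assert cp.p == cn.p
            assert cp.sign == -cn.sign

    def test_independent_design_detects_group_difference(self, adjacency32):
        patch = contiguous_patch(adjacency32, 2, 8)
        rng = np.random.default_rng(3)
        a = rng.standard_normal((25, 32))
        b = rng.standard_normal((25, 32))
        a[:, patch] += 1.0
        res = cluster_mass_test(a, b, adjacency32, design="independent", tail="two",
                                alpha=0.025, n_perm=200, rng=rng)
        sig = [c for c in res.significant() if c.sign > 0]
        assert sig
        assert len(set(sig[0].electrodes) & set(patch)) >= 4

    def test_deterministic_given_seed(self, adjacency32):
        rng_data = np.random.default_rng(4)
        a = rng_data.standard_normal((10, 32))
        b = rng_data.standard_normal((10, 32))
        r1 = cluster_mass_test(a, b, adjacency32, n_perm=100,
                               rng=np.random.default_rng(5))
        r2 = cluster_mass_test(a, b, adjacency32, n_perm=100,
                               rng=np.random.default_rng(5))
        assert [(c.electrodes, c.mass, c.p) for c in r1.clusters] == [
            (c.electrodes, c.mass, c.p) for c in r2.clusters
        ]

    def test_matches_mne_cluster_definition(self, adjacency32, rng):
        """Cross-check observed clusters and masses against MNE's
        permutation clustering on the same threshold and adjacency."""
        pytest.importorskip("mne")
        import mne.stats
        from scipy import sparse, stats as sps

        diffs = rng.standard_normal((18, 32))
        diffs[:, contiguous_patch(adjacency32, 7, 6)] += 0.9
        thr = float(sps.t.ppf(1 - 0.05, len(diffs) - 1))
        res = cluster_mass_test(diffs, np.zeros_like(diffs), adjacency32,
                                design="paired", tail="one", alpha=0.05,
                                min_size=1, n_perm=50, rng=rng)
        t_obs, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
            diffs, threshold=thr, tail=1,
            adjacency=sparse.csr_matrix(adjacency32.matrix),
            n_permutations=50, seed=1, out_type="indices", verbose="error",
        )
        np.testing.assert_allclose(res.t_map, t_obs, rtol=1e-10)
        mine = sorted(tuple(c.electrodes) for c in res.clusters)
        theirs = sorted(tuple(np.sort(c[0])) for c in clusters)
        assert mine == theirs
        mass_mine = sorted(round(c.mass, 9) for c in res.clusters)
        mass_theirs = sorted(round(float(t_obs[np.array(c[0])].sum()), 9) for c in clusters)
        assert mass_mine == mass_theirs

    def test_invalid_parameters_rejected(self, adjacency32, rng):
        a = rng.standard_normal((8, 32))
        with pytest.raises(InvalidParameterError):
            cluster_mass_test(a, a[:5], adjacency32, design="paired")
        with pytest.raises(InvalidParameterError):
            cluster_mass_test(a, a, adjacency32, alpha=0.7)
        with pytest.raises(InvalidParameterError):
            cluster_mass_test(a[:, :10], a[:, :10], adjacency32)
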