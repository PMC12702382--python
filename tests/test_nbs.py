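"""Network-based statistics: edge-wise t, components, permutation FWER."""

import numpy as np
import pytest

from foldconn import (
    NbsConfig,
    edge_class_breakdown,
    edgewise_t,
    gen_planted_edge_groups,
    nbs_test,
    suprathreshold_components,
)
from foldconn.connectivity import classify_edges
from foldconn.parcellation import FoldClass, RoiNode, RoiSet


def make_rois(n_gyral, n_sulcal):
    nodes = [
        RoiNode(region_id=i + 1, fold_class=FoldClass.GYRAL)
        for i in range(n_gyral)
    ] + [
        RoiNode(region_id=100 + i, fold_class=FoldClass.SULCAL)
        for i in range(n_sulcal)
    ]
    return RoiSet(nodes=nodes)


def sym_stack(rng, n_subj, n_nodes, shift=0.0):
    iu, ju = np.triu_indices(n_nodes, k=1)
    out = np.zeros((n_subj, n_nodes, n_nodes))
    vals = rng.standard_normal((n_subj, iu.size)) + shift
    out[:, iu, ju] = vals
    out[:, ju, iu] = vals
    return out


class TestEdgewiseT:
    def test_identical_groups_give_zero(self, rng):
        a = sym_stack(rng, 5, 6)
        t = edgewise_t(a, a.copy())
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_matches_textbook_pooled_t(self, rng):
        """Hand-listed edge values reproduce the pooled-variance formula."""
        a = sym_stack(rng, 5, 4)
        b = sym_stack(rng, 7, 4)
        t = edgewise_t(a, b)
        i, j = 1, 3
        xa, xb = a[:, i, j], b[:, i, j]
        na, nb = 5, 7
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (
            na + nb - 2
        )
        expected = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t[i, j] == pytest.approx(expected)

    def test_swapping_groups_negates(self, rng):
        a = sym_stack(rng, 6, 5)
        b = sym_stack(rng, 6, 5, shift=0.3)
        np.testing.assert_allclose(
            edgewise_t(a, b), -edgewise_t(b, a), atol=1e-12
        )

    def test_zero_variance_everywhere_gives_zero_not_nan(self):
        a = np.zeros((3, 4, 4))
        b = np.zeros((3, 4, 4))
        t = edgewise_t(a, b)
        assert np.isfinite(t).all() and (t == 0).all()


class TestComponents:
    def _matrix(self, n, edges, value=5.0):
        m = np.zeros((n, n))
        for i, j in edges:
            m[i, j] = m[j, i] = value
        return m

    def test_chain_is_one_component(self):
        comps = suprathreshold_components(
            self._matrix(5, [(1, 2), (2, 3)]), 3.1
        )
        assert len(comps) == 1
        assert comps[0].extent == 2
        assert comps[0].edges == [(1, 2), (2, 3)]

    def test_disjoint_edges_two_components(self):
        comps = suprathreshold_components(
            self._matrix(5, [(1, 2), (3, 4)]), 3.1
        )
        assert [c.extent for c in comps] == [1, 1]
        assert comps[0].edges == [(1, 2)]  # tie broken by smallest node

    def test_empty_result_allowed(self):
        assert suprathreshold_components(np.zeros((4, 4)), 3.1) == []

    def test_matches_unionfind_oracle(self, rng):
        """Random graphs agree with an independent union-find grouping."""
        for _ in range(20):
            n = 12
            t = np.zeros((n, n))
            iu, ju = np.triu_indices(n, k=1)
            vals = rng.normal(size=iu.size) * 3
            t[iu, ju] = t[ju, iu] = vals
            comps = suprathreshold_components(t, 3.1)

            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            kept = [(i, j) for i, j in zip(iu, ju) if t[i, j] > 3.1]
            for i, j in kept:
                parent[find(i)] = find(j)
            groups = {}
            for i, j in kept:
                groups.setdefault(find(i), []).append((i, j))
            oracle = sorted(
                (sorted(es) for es in groups.values()),
                key=lambda es: (-len(es), min(min(e) for e in es)),
            )
            assert [c.edges for c in comps] == oracle

    def test_raising_threshold_never_grows_extent(self, rng):
        t = np.abs(sym_stack(rng, 1, 15)[0]) * 4
        lo = suprathreshold_components(t, 2.0)
        hi = suprathreshold_components(t, 3.0)
        max_lo = lo[0].extent if lo else 0
        max_hi = hi[0].extent if hi else 0
        assert max_hi <= max_lo


class TestNbsTest:
    def test_identical_groups_no_significant_components(self, rng):
        a = sym_stack(rng, 5, 10)
        res = nbs_test(a, a.copy(), NbsConfig(n_perm=50, seed=0))
        assert res.components == []

    def test_planted_block_recovered(self):
        """A 1.5-SD shifted 8-node block is detected with p_fwe < 0.05 in
        at least 90% of generator seeds."""
        block = list(range(8))
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            a, b, truth = gen_planted_edge_groups(
                20, 64, block, shift=1.5, seed=seed
            )
            res = nbs_test(a, b, NbsConfig(n_perm=500, seed=1000 + seed))
            found = any(
                c.significant and set(c.nodes) & set(block)
                for c in res.components
            )
            hits += found
        assert hits >= 0.9 * n_seeds

    def test_reproducible_null_from_seed(self, rng):
        a = sym_stack(rng, 6, 12)
        b = sym_stack(rng, 6, 12)
        r1 = nbs_test(a, b, NbsConfig(n_perm=100, seed=42))
        r2 = nbs_test(a, b, NbsConfig(n_perm=100, seed=42))
        np.testing.assert_array_equal(r1.null_max_extents, r2.null_max_extents)

    def test_subject_order_invariance(self, rng):
        a = sym_stack(rng, 8, 10, shift=0.5)
        b = sym_stack(rng, 8, 10)
        perm = rng.permutation(8)
        r1 = nbs_test(a, b, NbsConfig(n_perm=50, seed=3))
        r2 = nbs_test(a[perm], b, NbsConfig(n_perm=50, seed=3))
        np.testing.assert_allclose(r1.t_matrix, r2.t_matrix, atol=1e-10)

    def test_p_fwe_monotone_in_extent(self, rng):
        a = sym_stack(rng, 10, 20, shift=0.8)
        b = sym_stack(rng, 10, 20)
        res = nbs_test(a, b, NbsConfig(n_perm=200, seed=7, t_threshold=2.0))
        extents = [c.extent for c in res.components]
        ps = [c.p_fwe for c in res.components]
        for (e1, p1), (e2, p2) in zip(
            zip(extents, ps), zip(extents[1:], ps[1:])
        ):
            assert e1 >= e2 and p1 <= p2

    def test_global_null_rank_uniformity(self):
        """With already-random labels the observed max extent is a draw
        from the null: its permutation rank is roughly uniform."""
        ranks = []
        for seed in range(40):
            a, b = _null_pair(seed)
            res = nbs_test(
                a, b, NbsConfig(n_perm=99, seed=10_000 + seed, t_threshold=2.5)
            )
            obs = (
                res.components[0].extent if res.components else 0
            )
            ranks.append((res.null_max_extents >= obs).mean())
        # ranks live in [0,1]; under the null their mean is near 1/2
        assert 0.25 < np.mean(ranks) < 0.75

    def test_invalid_nperm_rejected(self, rng):
        a = sym_stack(rng, 3, 5)
        with pytest.raises(ValueError, match="n_perm"):
            NbsConfig(n_perm=0)


def _null_pair(seed):
    from foldconn import gen_null_edge_groups

    return gen_null_edge_groups(12, 24, seed=seed)


class TestEdgeClassBreakdown:
    def test_counts_by_construction(self):
        rois = make_rois(2, 2)  # nodes 0,1 gyral; 2,3 sulcal
        classes = classify_edges(rois)
        assert edge_class_breakdown([(0, 1)], classes) == {
            "GG": 1,
            "GS": 0,
            "SS": 0,
        }
        out = edge_class_breakdown([(0, 2), (1, 2), (2, 3)], classes)
        assert out == {"GG": 0, "GS": 2, "SS": 1}

    def test_planted_gs_only_effect(self):
        """A connected effect planted purely on GS edges comes back as a
        component whose breakdown is all-GS."""
        rois = make_rois(32, 32)  # nodes 0..31 gyral, 32..63 sulcal
        classes = classify_edges(rois)
        gs_block = [(i, 32 + j) for i in range(3) for j in range(3)]
        rng = np.random.default_rng(5)
        a = sym_stack(rng, 20, 64)
        b = sym_stack(rng, 20, 64)
        for i, j in gs_block:
            a[:, i, j] += 2.0
            a[:, j, i] += 2.0
        res = nbs_test(
            a, b, NbsConfig(n_perm=100, seed=9, t_threshold=4.0)
        )
        assert res.components
        comp = res.components[0]
        assert set(gs_block) <= set(comp.edges)
        counts = edge_class_breakdown(comp.edges, classes)
        assert counts["GS"] == comp.extent
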