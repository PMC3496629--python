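"""Nei distance, shared-site selection, neighbor-joining and rooting."""

import math

import dendropy
import numpy as np
import pytest

from divscan import genetic_distance as gd
from divscan import variant_filtering as vf


class TestNeiDistance:
    def test_hand_derived_two_locus_example(self):
        # x hom_ref at both loci; y het at locus 1, hom_ref at locus 2:
        # J_X = 1, J_Y = 0.75, J_XY = 0.75 -> D = -ln(0.75/sqrt(0.75))
        x = np.array([1.0, 1.0])
        y = np.array([0.5, 1.0])
        expected = -math.log(0.75 / math.sqrt(0.75))
        assert gd.nei_distance(x, y) == pytest.approx(expected, abs=1e-12)
        assert gd.nei_distance(x, y) == pytest.approx(0.14384103622589045,
                                                      abs=1e-12)

    def test_identity_and_symmetry(self, rng):
        x = rng.choice([0.0, 0.5, 1.0], size=200)
        y = rng.choice([0.0, 0.5, 1.0], size=200)
        assert gd.nei_distance(x, x) == 0.0
        assert gd.nei_distance(x, y) == gd.nei_distance(y, x)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(1000):
            x = rng.choice([0.0, 0.5, 1.0], size=50)
            y = rng.choice([0.0, 0.5, 1.0], size=50)
            d = gd.nei_distance(x, y)
            assert d >= 0.0 or math.isinf(d)

    def test_loci_missing_in_one_individual_are_excluded(self, rng):
        x = rng.choice([0.0, 0.5, 1.0], size=60)
        y = rng.choice([0.0, 0.5, 1.0], size=60)
        base = gd.nei_distance(x, y)
        x2 = np.concatenate([x, [0.5, 1.0, np.nan]])
        y2 = np.concatenate([y, [np.nan, np.nan, 0.0]])
        assert gd.nei_distance(x2, y2) == base

    def test_no_shared_loci_is_undefined(self):
        assert math.isnan(gd.nei_distance(np.array([np.nan]),
                                          np.array([0.5])))


class TestSharedSites:
    def test_threshold_boundary(self, small_sim):
        table, _, _, pm = small_sim
        cls = vf.classify_sites(table, pm)
        mask = gd.select_shared_sites(cls, k=9)
        assert np.all(cls.n_populations_called[mask] >= 9)
        assert np.all(cls.n_populations_called[~mask] < 9)
        # brute-force recount on a sample of sites
        for i in range(0, table.n_sites, 997):
            called = np.sum(cls.status[i] != vf.ABSENT)
            assert mask[i] == (called >= 9)

    def test_segregating_mode_is_stricter(self, small_sim):
        table, _, _, pm = small_sim
        cls = vf.classify_sites(table, pm)
        called = gd.select_shared_sites(cls, k=9, mode="called")
        seg = gd.select_shared_sites(cls, k=9, mode="segregating")
        assert seg.sum() <= called.sum()
        assert np.all(called[seg])


def _random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree as a networkx graph; returns the graph,
    leaf names, and the exact leaf-to-leaf path-length matrix (the oracle)."""
    import networkx as nx

    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_taxa)]
    g.add_node("v0")
    for leaf in labels[:3]:
        g.add_edge("v0", leaf, length=float(rng.uniform(0.05, 1.0)))
    next_internal = 1
    for leaf in labels[3:]:
        u, v = list(g.edges)[rng.integers(0, g.number_of_edges())]
        length = g.edges[u, v]["length"]
        w = f"v{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        g.remove_edge(u, v)
        g.add_edge(u, w, length=split)
        g.add_edge(w, v, length=length - split)
        g.add_edge(w, leaf, length=float(rng.uniform(0.05, 1.0)))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    matrix = np.array([[dist[a][b] for b in labels] for a in labels])
    return labels, matrix


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = gd.DistanceMatrix(["A", "B", "C"],
                               np.array([[0.0, 3.0, 4.0],
                                         [3.0, 0.0, 5.0],
                                         [4.0, 5.0, 0.0]]))
        tree = gd.neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_recovers_random_additive_trees_exactly(self, rng):
        """Path-length matrices of NJ trees built from additive matrices
        equal the generating matrices (topology and branch lengths)."""
        for rep in range(100):
            n = int(rng.integers(4, 9))
            labels, matrix = _random_additive_tree(rng, n)
            tree = gd.neighbor_joining(gd.DistanceMatrix(labels, matrix))
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, a in enumerate(labels):
                for j in range(i + 1, n):
                    b = labels[j]
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        matrix[i, j], abs=1e-8)

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        labels, matrix = _random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        tree1 = gd.neighbor_joining(gd.DistanceMatrix(labels, matrix))
        tree2 = gd.neighbor_joining(gd.DistanceMatrix(
            [labels[i] for i in perm], matrix[np.ix_(perm, perm)]))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=tree1.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t2 = dendropy.Tree.get(data=tree2.as_string(schema="newick"),
                               schema="newick", taxon_namespace=tns,
                               preserve_underscores=True)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestRooting:
    def _quartet(self):
        return dendropy.Tree.get(data="(A:1,B:1,(C:1,D:1):1);",
                                 schema="newick", preserve_underscores=True)

    def test_outgroup_becomes_sister_to_rest(self):
        rooted = gd.root_at_outgroup(self._quartet(), ["A"])
        kids = rooted.seed_node.child_nodes()
        sides = [sorted(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert ["A"] in sides
        assert sorted(sides, key=len)[1] == ["B", "C", "D"]

    def test_rooting_is_idempotent(self):
        r1 = gd.root_at_outgroup(self._quartet(), ["C", "D"])
        r2 = gd.root_at_outgroup(r1, ["C", "D"])
        assert r1.as_string(schema="newick") == r2.as_string(schema="newick")

    def test_wild_individuals_form_basal_clade_on_simulation(self, small_sim):
        table, _, _, pm = small_sim
        cls = vf.classify_sites(table, pm)
        mask = gd.select_shared_sites(cls, k=9)
        idx = np.where(mask)[0][::8]   # thin for speed; plenty of loci remain
        sub = type(table)(table.samples, table.contigs[idx], table.pos[idx],
                          table.ref[idx], table.alt[idx], table.gt[idx],
                          table.gq[idx], table.dp[idx], table.contig_lengths)
        dm = gd.nei_distance_matrix(sub, pm)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        tree = gd.neighbor_joining(dm)
        rooted = gd.root_at_outgroup(tree, pm.samples_in("SM"))
        kids = rooted.seed_node.child_nodes()
        sides = [set(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert {"SMa", "SMb", "SMc"} in sides
        # individuals of each simulated population cluster together
        pdm = rooted.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in rooted.taxon_namespace}
        within = [pdm.distance(taxa["L3a"], taxa["L3b"])]
        between = [pdm.distance(taxa["L3a"], taxa["L5a"]),
                   pdm.distance(taxa["L3a"], taxa["BvSWa"])]
        assert max(within) < min(between)
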