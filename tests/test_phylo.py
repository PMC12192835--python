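"""Neighbor joining, bootstrap supports, rooting, Newick round trips."""

import io
import random

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from plastobarcode import barcode, phylo


def _dm(labels, values):
    values = np.asarray(values, dtype=float)
    return barcode.DistanceMatrix(labels, values, np.zeros_like(values, dtype=bool))


def _random_additive(seed, ntax):
    """A random tree plus its exact path-length distance matrix."""
    labels = [f"t{i}" for i in range(ntax)]
    tns = dendropy.TaxonNamespace(labels)
    rng = np.random.default_rng(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        1.0, 0.0, num_extant_tips=ntax, taxon_namespace=tns,
        rng=random.Random(seed),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    M = np.array(
        [[pdm.distance(tns.get_taxon(a), tns.get_taxon(b)) for b in labels]
         for a in labels]
    )
    return tree, tns, _dm(labels, M)


def test_three_taxon_branch_lengths_solve_three_point_formulas():
    dm = _dm(["a", "b", "c"], [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = phylo.nj_tree(dm)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(0.5 * (0.4 + 0.6 - 0.8))
    assert lengths["b"] == pytest.approx(0.5 * (0.4 + 0.8 - 0.6))
    assert lengths["c"] == pytest.approx(0.5 * (0.6 + 0.8 - 0.4))


def test_nj_recovers_random_additive_topologies():
    for seed in range(25):
        ntax = 4 + seed % 9
        true_tree, tns, dm = _random_additive(seed, ntax)
        nj = phylo.nj_tree(dm)
        nj.migrate_taxon_namespace(tns)
        true_tree.deroot()
        true_tree.update_bipartitions()
        nj.update_bipartitions()
        assert treecompare.symmetric_difference(true_tree, nj) == 0


def test_nj_agrees_with_dendropy_reference_implementation():
    """Cross-check against dendropy's own NJ on random (non-additive)
    matrices: same unrooted topology."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        ntax = int(rng.integers(4, 9))
        labels = [f"t{i}" for i in range(ntax)]
        M = rng.uniform(0.2, 1.0, size=(ntax, ntax))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        mine = phylo.nj_tree(_dm(labels, M))

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(M[i, j]) for j in range(ntax))
            for i in range(ntax)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv),
            taxon_namespace=dendropy.TaxonNamespace(labels),
        )
        ref = pdm.nj_tree()
        mine.migrate_taxon_namespace(ref.taxon_namespace)
        ref.deroot()
        ref.update_bipartitions()
        mine.update_bipartitions()
        assert treecompare.symmetric_difference(ref, mine) == 0


def test_ultrametric_four_taxon_matrix_matches_upgma_split():
    # ((a,b),(c,d)) with ultrametric heights
    M = [
        [0.0, 0.2, 1.0, 1.0],
        [0.2, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.4],
        [1.0, 1.0, 0.4, 0.0],
    ]
    tree = phylo.nj_tree(_dm(list("abcd"), M))
    splits = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node and not nd.is_leaf():
            splits.add(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
    assert frozenset("ab") in splits or frozenset("cd") in splits


def test_undefined_matrix_entries_rejected():
    values = np.array([[0, 0.1, 0.1], [0.1, 0, 0.1], [0.1, 0.1, 0]])
    undef = np.zeros_like(values, dtype=bool)
    undef[0, 1] = undef[1, 0] = True
    with pytest.raises(ValueError, match="undefined"):
        phylo.nj_tree(barcode.DistanceMatrix(list("abc"), values, undef))


def test_negative_branch_estimates_clamped_to_zero():
    # a matrix engineered to yield a negative NJ branch estimate
    M = [
        [0.0, 0.1, 0.4, 0.45],
        [0.1, 0.0, 0.45, 0.4],
        [0.4, 0.45, 0.0, 0.1],
        [0.45, 0.4, 0.1, 0.0],
    ]
    tree = phylo.nj_tree(_dm(list("abcd"), M))
    for e in tree.preorder_edge_iter():
        assert e.length is None or e.length >= 0


def _two_clade_alignment(n_diag=50, length=300, per_clade=3, seed=0):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), length))
    other = list(base)
    for i in range(n_diag):
        other[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[i]]
    al = {}
    for t in range(per_clade):
        a = list(base)
        b = list(other)
        a[length - 1 - t] = "A" if a[length - 1 - t] != "A" else "C"
        b[length - 20 - t] = "A" if b[length - 20 - t] != "A" else "C"
        al[f"A{t}"] = "".join(a)
        al[f"B{t}"] = "".join(b)
    return al


def test_bootstrap_is_deterministic_given_seed():
    al = _two_clade_alignment()
    t1 = phylo.bootstrap_tree(al, replicates=60, seed=9)
    t2 = phylo.bootstrap_tree(al, replicates=60, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_planted_clade_gets_high_support():
    al = _two_clade_alignment(n_diag=50)
    tree = phylo.bootstrap_tree(al, replicates=200, seed=3)
    clades = {}
    leaves = frozenset(al)
    for nd in tree.preorder_node_iter():
        if nd.parent_node and not nd.is_leaf():
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if "A0" in side:
                side = leaves - side
            clades[side] = nd.annotations.get_value("support")
    split = frozenset({"B0", "B1", "B2"})
    assert split in clades
    assert clades[split] >= 99.0


def test_bootstrap_supports_invariant_to_label_order():
    al = _two_clade_alignment()
    rev = dict(reversed(list(al.items())))
    t1 = phylo.bootstrap_tree(al, replicates=80, seed=5)
    t2 = phylo.bootstrap_tree(rev, replicates=80, seed=5)

    def supports(tree):
        leaves = frozenset(al)
        out = {}
        for nd in tree.preorder_node_iter():
            if nd.parent_node and not nd.is_leaf():
                side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if "A0" in side:
                    side = leaves - side
                out[side] = nd.annotations.get_value("support")
        return out

    s1, s2 = supports(t1), supports(t2)
    split = frozenset({"B0", "B1", "B2"})
    assert abs(s1[split] - s2[split]) < 15  # same signal, resampling noise only


def test_root_with_single_leaf_outgroup_on_pendant_edge():
    _, tns, dm = _random_additive(5, 6)
    tree = phylo.nj_tree(dm)
    rooted = phylo.root_with_outgroup(tree, ["t0"])
    children = rooted.seed_node.child_nodes()
    assert len(children) == 2
    sides = [frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in children]
    assert frozenset({"t0"}) in sides


def _leaf_path_length(tree, label_a, label_b):
    """Path length between two leaves, by walking to the seed node."""

    def path_to_root(label):
        nd = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == label)
        out = []
        while nd.parent_node is not None:
            out.append((id(nd), nd.edge.length or 0.0))
            nd = nd.parent_node
        return out

    pa, pb = path_to_root(label_a), path_to_root(label_b)
    ids_b = {i for i, _ in pb}
    shared = [i for i, _ in pa if i in ids_b]
    # drop the shared suffix (edges above the MRCA appear in both paths)
    da = sum(l for i, l in pa if i not in ids_b)
    ids_a = {i for i, _ in pa}
    db = sum(l for i, l in pb if i not in ids_a)
    return da + db


def test_rooting_preserves_total_tree_length_and_leaf_paths():
    _, tns, dm = _random_additive(8, 7)
    tree = phylo.nj_tree(dm)
    total_before = sum(e.length or 0 for e in tree.preorder_edge_iter())
    d_before = _leaf_path_length(tree, "t1", "t2")
    rooted = phylo.root_with_outgroup(tree, ["t0"])
    total_after = sum(e.length or 0 for e in rooted.preorder_edge_iter())
    assert total_after == pytest.approx(total_before)
    assert _leaf_path_length(rooted, "t1", "t2") == pytest.approx(d_before)


def test_planted_outgroup_split_recovered(small_dataset):
    al = _two_clade_alignment(n_diag=60)
    tree = phylo.bootstrap_tree(al, replicates=50, seed=1)
    rooted = phylo.root_with_outgroup(tree, ["B0", "B1", "B2"])
    sides = [
        frozenset(lf.taxon.label for lf in c.leaf_iter())
        for c in rooted.seed_node.child_nodes()
    ]
    assert frozenset({"B0", "B1", "B2"}) in sides


def test_newick_round_trip_preserves_topology_lengths_supports(tmp_path):
    al = _two_clade_alignment()
    tree = phylo.bootstrap_tree(al, replicates=40, seed=2)
    path = tmp_path / "t.nwk"
    phylo.write_newick(tree, path)
    back = phylo.read_newick(path)
    back.migrate_taxon_namespace(tree.taxon_namespace)
    t1 = tree.clone(depth=1)
    t1.update_bipartitions()
    back.update_bipartitions()
    assert treecompare.symmetric_difference(t1, back) == 0
    # lengths preserved to 6 decimals, supports as internal labels
    lengths1 = sorted(round(e.length, 6) for e in tree.preorder_edge_iter() if e.length)
    lengths2 = sorted(round(e.length, 6) for e in back.preorder_edge_iter() if e.length)
    assert lengths1 == lengths2
    labels1 = sorted(nd.label for nd in tree.preorder_node_iter()
                     if nd.label and not nd.is_leaf())
    labels2 = sorted(nd.label for nd in back.preorder_node_iter()
                     if nd.label and not nd.is_leaf())
    assert labels1 == labels2


def test_simple_newick_parses_and_malformed_raises(tmp_path):
    p = tmp_path / "ok.nwk"
    p.write_text("(A,B,(C,D));\n")
    tree = phylo.read_newick(p)
    internal = [nd for nd in tree.preorder_node_iter()
                if nd.parent_node and not nd.is_leaf()]
    assert len(internal) == 1
    p2 = tmp_path / "sci.nwk"
    p2.write_text("(A:1e-3,B:0.2,(C:0.1,D:0.1):0.05);\n")
    t2 = phylo.read_newick(p2)
    lf = next(l for l in t2.leaf_node_iter() if l.taxon.label == "A")
    assert lf.edge.length == pytest.approx(1e-3)
    bad = tmp_path / "bad.nwk"
    bad.write_text("(A,B,(C,D;\n")
    with pytest.raises(ValueError, match="malformed"):
        phylo.read_newick(bad)
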