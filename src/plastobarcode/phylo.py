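"""Neighbor-joining trees with column-resampling bootstrap and rooting.

NJ follows the Saitou-Nei agglomeration; a negative branch-length estimate
is clamped to zero with the deficit moved to its sister edge so the joined
pair keeps its estimated total.  Trees are dendropy ``Tree`` objects, so
Newick I/O, rerooting and topology comparison interoperate with the wider
phylogenetics ecosystem.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .barcode import DistanceMatrix, k2p_matrix

log = logging.getLogger(__name__)


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from a distance matrix.

    Raises if the matrix has undefined (masked) entries; mask or impute
    upstream before tree building.
    """
    if np.any(matrix.undefined):
        raise ValueError("distance matrix has undefined entries; mask or impute upstream")
    labels = list(matrix.labels)
    m = len(labels)
    if m < 3:
        raise ValueError("need at least three taxa")

    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    D = matrix.values.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), k)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [t for t in range(k) if t not in (i, j)]
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[t] for t in keep] + [parent]

    # final three-way join (three-point formulas)
    a, b, c = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for nd, ln in zip(nodes, (la, lb, lc)):
        nd.edge.length = max(0.0, ln)
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised to the side not containing the
    alphabetically first taxon."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    first = leaves[0]
    all_set = frozenset(leaves)
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if first in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_tree(
    alignment: dict[str, str], replicates: int, seed: int
) -> dendropy.Tree:
    """Full-data NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement; each replicate gets a K2P
    matrix and NJ tree; bipartition frequencies (%) are attached to the
    full-data tree's internal nodes (``support`` annotation and label).
    Deterministic for a fixed seed.
    """
    full = nj_tree(k2p_matrix(alignment))
    labels = list(alignment)
    arr = np.array([list(alignment[l]) for l in labels])
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    used = 0
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        res = {lab: "".join(row) for lab, row in zip(labels, arr[:, idx])}
        dm = k2p_matrix(res)
        if np.any(dm.undefined):
            continue  # saturated replicate: no usable tree
        used += 1
        for bp in _bipartitions(nj_tree(dm)):
            counts[bp] = counts.get(bp, 0) + 1

    leaves = sorted(alignment)
    first = leaves[0]
    all_set = frozenset(leaves)
    for nd in full.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if first in side:
            side = all_set - side
        if not (2 <= len(side) <= len(leaves) - 2):
            continue
        support = 100.0 * counts.get(side, 0) / used if used else float("nan")
        nd.label = f"{support:.0f}" if used else ""
        nd.annotations["support"] = support
    return full


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels: list[str]) -> dendropy.Tree:
    """Root on the edge separating the smallest clade holding the outgroup.

    A non-monophyletic outgroup is handled by rooting on the edge whose
    taxon side best overlaps the outgroup set, with a warning.
    """
    tree = tree.clone(depth=1)
    out = set(outgroup_labels)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = out - leaves
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")

    best = None
    mono = False
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        for cand in (side, leaves - side):
            score = len(cand & out) - len(cand - out)
            key = (score, -len(cand), id(nd))
            if best is None or key > best[0]:
                best = (key, nd)
                mono = cand == out
    if not mono:
        log.warning("outgroup %s is not monophyletic; rooting on best-overlap edge", sorted(out))
    node = best[1]
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str) -> None:
    """Newick output with supports as internal node labels, 6-decimal
    branch lengths."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )


def read_newick(path: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
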