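"""Neighbour-joining trees, bootstrap support and monophyly assessment.

NJ follows the classical Saitou-Nei/Studier-Keppler agglomeration on the
Q-matrix; ties are broken deterministically by the lexicographically
smallest joined pair (each internal node carries the smallest leaf label in
its subtree as sort key). Negative branch lengths are clamped to zero with
the deficit moved to the sister edge. The result is an unrooted tree whose
seed node is the final trifurcation.

Bootstrap support resamples alignment columns with replacement, recomputes
K2P + NJ per replicate, and scores each bipartition of the reference tree by
the fraction of replicate trees containing it.

Monophyly of a cluster is assessed as: on a rooted tree, some node's
descendant leaf set equals the cluster; on an unrooted tree with an
outgroup, the cluster is one side of a bipartition and disjoint from the
outgroup (equivalent to rooting on the outgroup edge); ``rooting="unrooted"``
drops the outgroup requirement and accepts any bipartition side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .distances import DistanceMatrix, encode_matrix
from .errors import IntegrityError, ParameterError, RootingError
from .io_model import AlignedMatrix, Partition, TreeModel


def nj_tree(dm: DistanceMatrix) -> TreeModel:
    """Neighbour-joining tree from a distance matrix (unrooted)."""
    n = dm.n
    if n < 3:
        raise ParameterError("neighbour joining needs at least 3 specimens")
    if not np.all(np.isfinite(dm.d)):
        raise IntegrityError("distance matrix contains missing values")
    tns = dendropy.TaxonNamespace(dm.specimen_ids)
    nodes: List[dendropy.Node] = []
    keys: List[str] = []
    for sid in dm.specimen_ids:
        node = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(node)
        keys.append(sid)
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def _clamped(li: float, lj: float) -> Tuple[float, float]:
        # clamp negatives to 0, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamped(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_key = min(keys[i], keys[j])
        # reuse slot i for the merged node
        for k in active:
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        keys[i] = new_key
        active.remove(j)
    # final three-way join (three-point formulas)
    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    center = dendropy.Node()
    for idx, length in ((x, lx), (y, ly), (z, lz)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return TreeModel(tree)


def _leaf_sets(tree: dendropy.Tree) -> Dict[dendropy.Node, FrozenSet[str]]:
    sets: Dict[dendropy.Node, FrozenSet[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: Set[str] = set()
            for ch in node.child_nodes():
                acc |= sets[ch]
            sets[node] = frozenset(acc)
    return sets


def bipartitions(tree_model: TreeModel) -> Dict[FrozenSet[str], dendropy.Node]:
    """Non-trivial bipartition sides (as the child-side leaf set) -> node."""
    tree = tree_model.tree
    sets = _leaf_sets(tree)
    all_leaves = sets[tree.seed_node]
    out: Dict[FrozenSet[str], dendropy.Node] = {}
    for node, s in sets.items():
        if node is tree.seed_node:
            continue
        if 2 <= len(s) <= len(all_leaves) - 2:
            out[s] = node
    return out


def _normalized_splits(tree_model: TreeModel) -> Set[FrozenSet[str]]:
    """Bipartitions normalized to the side not containing a reference leaf."""
    leaves = frozenset(tree_model.leaf_labels)
    ref = min(leaves)
    out: Set[FrozenSet[str]] = set()
    for side in bipartitions(tree_model):
        out.add(frozenset(leaves - side) if ref in side else side)
    return out


def bootstrap_support(
    alignment: AlignedMatrix,
    replicates: int = 1000,
    seed: Optional[int] = None,
    reference: Optional[TreeModel] = None,
) -> Dict[FrozenSet[str], float]:
    """Column-resampling bootstrap support for NJ bipartitions.

    Returns support (fraction of replicates, in [0, 1]) for every non-trivial
    bipartition of the reference tree (the NJ tree of the full alignment by
    default). Bipartitions are keyed by the side not containing the
    lexicographically smallest specimen id.
    """
    from .distances import distance_matrix

    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    dm = distance_matrix(alignment)
    ref_tree = reference if reference is not None else nj_tree(dm)
    targets = _normalized_splits(ref_tree)
    counts = {s: 0 for s in targets}
    codes = encode_matrix(alignment)
    ids = list(alignment.specimen_ids)
    for _ in range(replicates):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        boot = AlignedMatrix(
            ids, ["".join("ACGT-N"[c] for c in row) for row in codes[:, cols]]
        )
        try:
            bdm = distance_matrix(boot)
            btree = nj_tree(bdm)
        except Exception:
            continue  # unusable replicate (saturation etc.) scores nothing
        found = _normalized_splits(btree)
        for s in targets:
            if s in found:
                counts[s] += 1
    return {s: counts[s] / replicates for s in targets}


@dataclass
class MonophylyReport:
    """Per-cluster monophyly verdicts for one tested partition.

    ``status`` is one of ``monophyletic``, ``non-monophyletic``, ``trivial``
    (size 1) and ``unresolvable`` (leaves missing from the tree);
    ``support`` is the bootstrap/posterior support of the cluster's node
    when available.
    """

    status: Dict[str, str]
    support: Dict[str, Optional[float]]

    def is_monophyletic(self, label: str, count_trivial: bool = True) -> bool:
        s = self.status[label]
        return s == "monophyletic" or (count_trivial and s == "trivial")


def _node_support(node: dendropy.Node) -> Optional[float]:
    label = getattr(node, "label", None)
    if label is None:
        return None
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


def monophyly(
    tree_model: TreeModel,
    partition: Partition,
    outgroup: Optional[Set[str]] = None,
    rooting: str = "auto",
    support_map: Optional[Dict[FrozenSet[str], float]] = None,
) -> MonophylyReport:
    """Assess each cluster of a partition for monophyly on a tree.

    ``rooting='auto'`` uses the tree's own rooting if bifurcating, else the
    outgroup (from the argument or the tree model); ``'unrooted'`` accepts
    any bipartition side as a clade, which is the natural criterion for
    unrooted NJ/ML trees when every candidate cluster is a proper subset of
    the leaves.
    """
    if rooting not in ("auto", "unrooted"):
        raise ParameterError(f"rooting must be 'auto' or 'unrooted', got {rooting!r}")
    leaves = set(tree_model.leaf_labels)
    og = set(outgroup) if outgroup else (tree_model.outgroup or set())
    status: Dict[str, str] = {}
    support: Dict[str, Optional[float]] = {}
    rooted = tree_model.is_rooted and not og
    if rooting == "auto" and not rooted and not og:
        raise RootingError("unrooted tree: supply an outgroup or rooting='unrooted'")
    if rooted:
        sets = _leaf_sets(tree_model.tree)
        clades = {s: node for node, s in sets.items()}
    else:
        clades = dict(bipartitions(tree_model))
    for label, members in partition.groups().items():
        mset = set(members)
        missing = mset - leaves
        if missing:
            status[label], support[label] = "unresolvable", None
            continue
        if len(mset) == 1:
            status[label], support[label] = "trivial", None
            continue
        fs = frozenset(mset)
        node = clades.get(fs)
        if node is None and not rooted:
            node = clades.get(frozenset(leaves - fs))  # matched as the parent side
        ok = node is not None
        if ok and not rooted and rooting == "auto" and og & mset:
            ok = False  # cluster overlaps the outgroup: cannot root outside it
        status[label] = "monophyletic" if ok else "non-monophyletic"
        sup = None
        if ok:
            sup = _node_support(node)
            if support_map is not None:
                ref = min(leaves)
                key = frozenset(leaves - fs) if ref in fs else fs
                sup = support_map.get(key, sup)
        support[label] = sup
    return MonophylyReport(status=status, support=support)
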