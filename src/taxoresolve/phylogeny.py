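"""Distance-based tree inference with bootstrap support.

Neighbor joining on 1-identity distances stands in for likelihood
inference: the downstream decision rules consume only topology, support
values, and branch lengths, and an externally inferred Newick tree can be
supplied instead at the CLI level.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional

import numpy as np

from .coregenome import ConcatenatedAlignment
from .tree import LabeledTree, TreeNode

log = logging.getLogger(__name__)

_GAP = ord("-")


def _encode_rows(alignment: ConcatenatedAlignment, level: str):
    if level not in ("protein", "nucleotide"):
        raise ValueError(f"unknown level {level!r}")
    source = alignment.protein if level == "protein" else alignment.nucleotide
    labels = list(alignment.strain_ids)
    codes = np.stack([
        np.frombuffer(source[s].encode(), dtype=np.uint8) for s in labels
    ])
    nongap = codes != _GAP
    core = np.zeros_like(nongap)
    for i in range(len(labels)):
        ng = nongap[i]
        if ng.any():
            lo = int(np.argmax(ng))
            hi = len(ng) - int(np.argmax(ng[::-1]))
            core[i, lo:hi] = True
    return labels, codes, nongap, core


def _pair_columns(codes, nongap, core, i, j, level="protein"):
    comparable = core[i] & core[j] & (nongap[i] | nongap[j])
    eq = (codes[i] == codes[j]) & nongap[i]
    ambiguous = b"N" if level == "nucleotide" else b"X"
    amb = np.isin(codes[i], np.frombuffer(ambiguous, dtype=np.uint8))
    matches = comparable & eq & ~amb
    return matches, comparable


def distance_matrix(alignment: ConcatenatedAlignment,
                    level: str = "protein") -> tuple[np.ndarray, list[str]]:
    """Pairwise 1-identity distances over the concatenated alignment."""
    labels, codes, nongap, core = _encode_rows(alignment, level)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 strains for a distance matrix")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matches, comparable = _pair_columns(codes, nongap, core, i, j,
                                               level)
            denom = int(comparable.sum())
            if denom == 0:
                raise ValueError(
                    f"no comparable columns for pair ({labels[i]}, {labels[j]})"
                )
            d = 1.0 - matches.sum() / denom
            dist[i, j] = dist[j, i] = d
    return dist, labels


def neighbor_joining(matrix: np.ndarray, labels: list[str]) -> LabeledTree:
    """Standard neighbor joining; exact on additive matrices.

    The returned tree is unrooted, stored with a trifurcating root.
    Negative branch-length estimates are clipped to zero (deficit logged).
    """
    D = np.array(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix/label shape mismatch")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if (D < -1e-9).any():
        raise ValueError("negative distances in input")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    def clipped(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                log.debug("negative NJ branch length %.3g clipped to 0", x)
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    if n == 2:
        a, b = nodes
        a.length = clipped(D[0, 1] / 2.0)
        b.length = clipped(D[0, 1] / 2.0)
        return LabeledTree(TreeNode(children=[a, b]))

    active = list(range(n))
    work = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # first minimum: deterministic tie rule
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        nodes[ai].length = clipped(li)
        nodes[aj].length = clipped(lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # Distances from the new node to the remaining taxa.
        new_row = np.zeros(work.shape[0] + 1)
        for pos, k in enumerate(active):
            if pos in (i, j):
                continue
            new_row[k] = 0.5 * (work[ai, k] + work[aj, k] - dij)
        work = np.pad(work, ((0, 1), (0, 1)))
        work[-1, :-1] = new_row[:-1]
        work[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (work[a, b] + work[a, c] - work[b, c])
    lb = 0.5 * (work[a, b] + work[b, c] - work[a, c])
    lc = 0.5 * (work[a, c] + work[b, c] - work[a, b])
    nodes[a].length = clipped(la)
    nodes[b].length = clipped(lb)
    nodes[c].length = clipped(lc)
    return LabeledTree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


# ------------------------------------------------------------- bipartitions

def bipartitions(tree: LabeledTree) -> dict[int, frozenset]:
    """Canonical unrooted bipartition per internal edge (node id keyed).

    Canonical side = the side not containing the first tip; trivial
    (single-tip / full-set) bipartitions are skipped.
    """
    all_tips = frozenset(tree.tip_names())
    anchor = min(all_tips)  # fixed anchor: canonical across topologies
    sets = tree.tipsets()
    parents = tree.parent_map()
    out = {}
    for node in tree.preorder():
        if node.is_leaf or parents[id(node)] is None:
            continue
        side = sets[id(node)]
        if anchor in side:
            side = all_tips - side
        if len(side) >= 2 and len(all_tips) - len(side) >= 2:
            out[id(node)] = side
    return out


def _bipartition_set(tree: LabeledTree) -> set[frozenset]:
    return set(bipartitions(tree).values())


def bootstrap_support(alignment: ConcatenatedAlignment,
                      n_replicates: int = 100,
                      seed: int = 42,
                      level: str = "protein") -> LabeledTree:
    """NJ tree with bootstrap support from column resampling."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, codes, nongap, core = _encode_rows(alignment, level)
    n = len(labels)
    n_cols = codes.shape[1]
    dist, _ = distance_matrix(alignment, level)
    main = neighbor_joining(dist, labels)

    # Per-pair per-column mismatch and comparability, for fast reweighting.
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mism = np.zeros((len(pairs), n_cols), dtype=np.float32)
    comp = np.zeros((len(pairs), n_cols), dtype=np.float32)
    for p, (i, j) in enumerate(pairs):
        matches, comparable = _pair_columns(codes, nongap, core, i, j, level)
        comp[p] = comparable
        mism[p] = comparable & ~matches

    rng = np.random.default_rng(seed)
    weights = rng.multinomial(
        n_cols, np.full(n_cols, 1.0 / n_cols), size=n_replicates
    ).T.astype(np.float32)
    num = mism @ weights
    den = comp @ weights
    with np.errstate(invalid="ignore", divide="ignore"):
        dists = np.where(den > 0, num / den, 1.0)

    counts: dict[frozenset, int] = defaultdict(int)
    for r in range(n_replicates):
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = dists[p, r]
        rep = neighbor_joining(d, labels)
        for bip in _bipartition_set(rep):
            counts[bip] += 1

    parts = bipartitions(main)
    parents = main.parent_map()
    for node in main.preorder():
        if node.is_leaf or parents[id(node)] is None:
            continue
        bip = parts.get(id(node))
        if bip is None:
            continue
        node.support = 100.0 * counts.get(bip, 0) / n_replicates
    return main


# --------------------------------------------------------- rooting/collapse

def _contract_unary(node: TreeNode) -> TreeNode:
    while len(node.children) == 1:
        only = node.children[0]
        merged = TreeNode(only.name,
                          (node.length or 0.0) + (only.length or 0.0)
                          if (node.length is not None or only.length is not None)
                          else None,
                          node.support if node.support is not None else only.support,
                          only.children)
        node = merged
    node.children = [_contract_unary(c) for c in node.children]
    return node


def _reroot_on_edge(tree: LabeledTree, target: TreeNode) -> LabeledTree:
    """Place the root at the midpoint of the edge above ``target``."""
    parents = tree.parent_map()
    parent = parents[id(target)]
    if parent is None:
        return tree.copy()
    adj: dict[int, list] = defaultdict(list)
    for node in tree.preorder():
        p = parents[id(node)]
        if p is not None:
            adj[id(node)].append((p, node.length, node.support))
            adj[id(p)].append((node, node.length, node.support))

    half = (target.length or 0.0) / 2.0
    sup = target.support

    def build(node: TreeNode, came_from: TreeNode,
              elen: Optional[float], esup: Optional[float]) -> TreeNode:
        new = TreeNode(node.name if node.is_leaf else None, elen, esup)
        for nb, l, s in adj[id(node)]:
            if nb is came_from:
                continue
            new.children.append(build(nb, node, l, s))
        return new

    root = TreeNode(children=[
        build(target, parent, half, sup),
        build(parent, target, half, sup),
    ])
    return LabeledTree(_contract_unary(root))


def root_with_outgroup(tree: LabeledTree, outgroup) -> LabeledTree:
    """Root the (possibly unrooted) tree on the outgroup edge."""
    og = frozenset(outgroup)
    all_tips = frozenset(tree.tip_names())
    missing = og - all_tips
    if missing:
        raise ValueError(f"outgroup tips not in tree: {sorted(missing)}")
    if og == all_tips:
        raise ValueError("outgroup covers the whole tree")
    sets = tree.tipsets()
    target = None
    for node in tree.preorder():
        s = sets[id(node)]
        if s == og or s == all_tips - og:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not monophyletic in the unrooted tree")
    if sets[id(target)] == all_tips - og and target is tree.root:
        # Root already separates the outgroup; reroot on a child edge.
        for child in tree.root.children:
            if sets[id(child)] == og:
                target = child
                break
    return _reroot_on_edge(tree, target)


def collapse_low_support(tree: LabeledTree,
                         threshold: float = 50.0) -> LabeledTree:
    """Contract every internal node with support below the threshold.

    Children of a collapsed node are promoted to its parent with the
    collapsed branch length added, preserving tip-to-root path lengths.
    Idempotent.
    """
    out = tree.copy()

    def walk(node: TreeNode) -> TreeNode:
        new_children = []
        for child in node.children:
            child = walk(child)
            if (not child.is_leaf and child.support is not None
                    and child.support < threshold):
                for gc in child.children:
                    gc.length = (gc.length or 0.0) + (child.length or 0.0)
                    new_children.append(gc)
            else:
                new_children.append(child)
        node.children = new_children
        return node

    return LabeledTree(walk(out.root))


def root_and_collapse(tree: LabeledTree, outgroup,
                      support_collapse: float = 50.0,
                      prune_outgroup: bool = False) -> LabeledTree:
    rooted = root_with_outgroup(tree, outgroup)
    collapsed = collapse_low_support(rooted, support_collapse)
    if prune_outgroup:
        collapsed = collapsed.prune(outgroup)
    return collapsed


# -------------------------------------------------------------- patristics

def patristic_distance(tree: LabeledTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique a-b path."""
    if a == b:
        tree.find_tip(a)
        return 0.0
    depths = tree.depths()
    node_a = tree.find_tip(a)
    node_b = tree.find_tip(b)
    anc = tree.mrca({a, b})
    return depths[id(node_a)] + depths[id(node_b)] - 2.0 * depths[id(anc)]


def patristic_matrix(tree: LabeledTree) -> tuple[np.ndarray, list[str]]:
    """All-pairs patristic distances by single postorder accumulation."""
    names = tree.tip_names()
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    dist = np.zeros((n, n))
    carried: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            carried[id(node)] = [(index[node.name], 0.0)]
            continue
        lists = []
        for child in node.children:
            lst = [(i, d + (child.length or 0.0))
                   for i, d in carried.pop(id(child))]
            lists.append(lst)
        for x in range(len(lists)):
            for y in range(x + 1, len(lists)):
                for i, di in lists[x]:
                    for j, dj in lists[y]:
                        dist[i, j] = dist[j, i] = di + dj
        carried[id(node)] = [item for lst in lists for item in lst]
    return dist, names
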