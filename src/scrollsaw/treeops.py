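"""Tree algorithms applied downstream of the distance/filtering stages.

* neighbor joining (via scikit-bio) as a desk-scale tree source,
* outgroup-free rooting by minimal ancestor deviation (MAD),
* paralog assignment by the smallest ancestral clade passing dual branch
  support thresholds (SH-aLRT and ultrafast bootstrap),
* Dollo parsimony gain/loss mapping of presence–absence patterns onto a
  rooted species tree.

Trees are :class:`dendropy.Tree` objects throughout; internal nodes may carry
``sh_alrt``/``ufboot`` attributes (see :mod:`scrollsaw.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "RootCandidate",
    "GainLossMap",
    "neighbor_joining",
    "mad_root",
    "assign_by_supported_clade",
    "dollo_map",
    "tip_distances",
]


def neighbor_joining(dm) -> dendropy.Tree:
    """Neighbor-joining tree from a :class:`~scrollsaw.evomodel.DistanceMatrix`.

    Negative estimated branch lengths are clamped to zero. Undefined (NaN)
    entries are rejected with a message naming the offending taxa.
    """
    import skbio

    bad = sorted({dm.ids[i] for i, j in zip(*np.where(np.isnan(dm.d)))})
    if bad:
        raise ValueError(
            f"distance matrix has undefined entries involving taxa {bad}; "
            "remove them before tree construction"
        )
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.ids)
    sk_tree = skbio.tree.nj(sk_dm)
    newick = str(sk_tree)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            node.edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# MAD rooting


@dataclass
class RootCandidate:
    """A candidate root position: a branch (identified by the tip set on its
    child side), the relative position ``rho`` in [0, 1] measured from the
    child node, and the root-mean-squared relative ancestor deviation."""

    branch: frozenset
    rho: float
    mad_score: float


def _node_distance_table(tree):
    """All node↔node path distances by BFS over the undirected topology."""
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj = [[] for _ in nodes]
    for n in nodes:
        if n.parent_node is not None:
            L = n.edge.length or 0.0
            adj[index[id(n)]].append((index[id(n.parent_node)], L))
            adj[index[id(n.parent_node)]].append((index[id(n)], L))
    dist = np.zeros((len(nodes), len(nodes)))
    for s in range(len(nodes)):
        seen = np.zeros(len(nodes), dtype=bool)
        seen[s] = True
        stack = [s]
        while stack:
            u = stack.pop()
            for v, L in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    dist[s, v] = dist[s, u] + L
                    stack.append(v)
    return nodes, index, dist


def tip_distances(tree) -> tuple[list[str], np.ndarray]:
    """Tip names and the matrix of patristic distances between tips."""
    nodes, index, dist = _node_distance_table(tree)
    tips = [n for n in nodes if n.is_leaf()]
    names = [t.taxon.label for t in tips]
    ix = [index[id(t)] for t in tips]
    return names, dist[np.ix_(ix, ix)]


def _branch_score(d_xc, L, d_cross, d_same_num, d_same_den):
    """Optimal rho and summed squared deviations for one branch.

    ``d_xc``: distances from cross-pair tips on the child side to the child
    node; ``d_cross``: the corresponding tip-tip distances; the same-side
    part is passed as precomputed deviation numerators/denominators.
    """
    a = 2.0 * d_xc / d_cross - 1.0
    b = 2.0 * L / d_cross
    bb = float((b * b).sum())
    rho = 0.5 if bb == 0 else float(-(a * b).sum() / bb)
    rho = min(max(rho, 0.0), 1.0)
    cross_ss = float(((a + b * rho) ** 2).sum())
    same_ss = float(((d_same_num / d_same_den) ** 2).sum())
    n_pairs = a.size + d_same_num.size
    return rho, cross_ss + same_ss, n_pairs


def mad_root(tree: dendropy.Tree):
    """Root a tree by the minimal ancestor deviation criterion.

    For each branch and each position ``rho`` along it, every tip pair
    deviates from the clocklike expectation by
    ``r = |2 * d(tip, ancestor) / d(tip, tip') - 1|``, where the ancestor is
    the candidate root for pairs straddling the branch and the pair's
    path-meeting node otherwise. The branch/position minimising the RMS of
    ``r`` (closed form in ``rho`` per branch) becomes the root.

    Returns ``(rooted_tree, best_candidate, all_candidates)``. Tip pairs with
    zero path distance are excluded with a warning. Ties are broken by the
    deterministic branch enumeration order.
    """
    work = tree.clone(depth=1)
    tip_names = [t.taxon.label for t in work.leaf_node_iter()]
    if len(tip_names) < 2:
        raise ValueError("MAD rooting requires >= 2 tips")
    if len(tip_names) == 2:
        # single unrooted branch; the clock point is its midpoint
        a, b = work.seed_node.child_nodes()
        L = (a.edge.length or 0.0) + (b.edge.length or 0.0)
        rho = 0.5 if L == 0 else (L / 2 - (a.edge.length or 0.0)) / L
        rho = min(max(rho, 0.0), 1.0)
        cand = RootCandidate(frozenset([a.taxon.label]), rho,
                             abs(2 * (L / 2) / L - 1.0) if L else 0.0)
        a.edge.length = L / 2
        b.edge.length = L / 2
        return work, cand, [cand]

    if len(work.seed_node.child_nodes()) == 2:
        work.deroot()
    nodes, index, dist = _node_distance_table(work)
    tips = [n for n in nodes if n.is_leaf()]
    tip_ix = np.array([index[id(t)] for t in tips])
    names = np.array([t.taxon.label for t in tips])
    n = len(tips)
    D = dist[np.ix_(tip_ix, tip_ix)]
    iu = np.triu_indices(n, k=1)
    if np.any(D[iu] == 0):
        warnings.warn("tip pairs at zero path distance excluded from MAD score")

    # tips below each node, as a boolean mask over the tip arrays
    below = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            m = names == node.taxon.label
        else:
            m = np.zeros(n, dtype=bool)
            for ch in node.child_nodes():
                m |= below[id(ch)]
        below[id(node)] = m

    candidates = []
    edge_nodes = []
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        L = node.edge.length or 0.0
        mask = below[id(node)]
        if mask.all() or not mask.any():
            continue
        side = mask[iu[0]].astype(int) + mask[iu[1]].astype(int)
        d_pair = D[iu]
        valid = d_pair > 0
        cross = (side == 1) & valid
        same = (side != 1) & valid
        # distance from the child-side tip of each cross pair to the child node
        ci = index[id(node)]
        d_to_child = dist[np.ix_(tip_ix, [ci])].ravel()
        x_tip = np.where(mask[iu[0]], iu[0], iu[1])[cross]
        d_xc = d_to_child[x_tip]
        # same-side pairs: meeting node m gives |d(x,m)-d(y,m)| / d(x,y)
        dx = d_to_child[iu[0][same]]
        dy = d_to_child[iu[1][same]]
        rho, ss, n_pairs = _branch_score(d_xc, L, d_pair[cross],
                                         np.abs(dx - dy), d_pair[same])
        score = np.sqrt(ss / n_pairs) if n_pairs else np.inf
        candidates.append(RootCandidate(frozenset(names[mask]), rho, float(score)))
        edge_nodes.append(node)

    best_i = int(np.argmin([c.mad_score for c in candidates]))
    best = candidates[best_i]
    node = edge_nodes[best_i]
    L = node.edge.length or 0.0
    rooted = _reroot_on_edge(work, node, best.rho * L)
    return rooted, best, candidates


def _reroot_on_edge(tree, child_node, dist_from_child):
    """Insert a root node on the edge above ``child_node`` at the given
    distance from it (toward the parent)."""
    L = child_node.edge.length or 0.0
    dist_from_child = min(max(dist_from_child, 0.0), L)
    parent = child_node.parent_node
    new_root = dendropy.Node()
    parent.remove_child(child_node)
    parent.add_child(new_root)
    new_root.edge.length = L - dist_from_child
    new_root.add_child(child_node)
    child_node.edge.length = dist_from_child
    tree.reseed_at(new_root, collapse_unrooted_basal_bifurcation=False)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# supported-clade assignment


def assign_by_supported_clade(
    tree: dendropy.Tree,
    query: str,
    refs: dict[str, str],
    *,
    sh_min: float = 80.0,
    ufboot_min: float = 95.0,
    composites: dict[frozenset, str] | None = None,
) -> str | None:
    """Assign a paralog label to ``query`` from the smallest well-supported
    ancestral clade containing reference sequences.

    Walking from the query tip toward the root, the first ancestor whose
    subtree holds at least one reference tip *and* whose branch support
    passes both thresholds (missing supports fail) defines the assignment
    clade. A single reference label yields that label; a label set matching a
    configured composite (e.g. ``{"Arf1", "Arf6"} → "Arf1/6"``) yields the
    composite; anything else — or no qualifying clade — yields ``None``.
    """
    composites = composites or {}
    leaf = None
    for t in tree.leaf_node_iter():
        if t.taxon.label == query:
            leaf = t
            break
    if leaf is None:
        raise KeyError(f"query tip {query!r} not in tree")

    node = leaf.parent_node
    while node is not None:
        labels = {refs[t.taxon.label]
                  for t in node.leaf_iter()
                  if t.taxon.label in refs}
        sh = getattr(node, "sh_alrt", None)
        uf = getattr(node, "ufboot", None)
        supported = (sh is not None and sh >= sh_min
                     and uf is not None and uf >= ufboot_min)
        if labels and supported:
            if len(labels) == 1:
                return next(iter(labels))
            return composites.get(frozenset(labels))
        node = node.parent_node
    return None


# ---------------------------------------------------------------------------
# Dollo gain/loss mapping


@dataclass
class GainLossMap:
    """Single-gain Dollo reconstruction of a presence–absence pattern.

    ``gain_clade`` and each loss edge are identified by the frozenset of
    scored tip names below them; ``n_losses`` is the minimum number of losses
    explaining the pattern given the gain placement.
    """

    paralog: str
    gain_clade: frozenset
    loss_edges: list[frozenset] = field(default_factory=list)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_map(
    tree: dendropy.Tree,
    present: set,
    absent: set,
    *,
    gain: str = "mrca",
    paralog: str = "",
) -> GainLossMap:
    """Minimum-loss Dollo mapping of a paralog's presence–absence pattern.

    Tips in neither set (e.g. transcriptome-only species scored as unknown)
    are ignored. The gain is placed at the MRCA of present tips
    (``gain="mrca"``) or at the root (``gain="root"``, for paralogs assumed
    ancestral); losses are the stem edges of the maximal clades below the
    gain whose scored tips are all absent. This greedy placement is the
    unique minimum under a single-gain model.
    """
    present, absent = set(present), set(absent)
    if not present:
        raise ValueError("no present tips: gain is not placeable")
    if gain not in {"mrca", "root"}:
        raise ValueError(f"unknown gain mode {gain!r}")
    tip_names = {t.taxon.label for t in tree.leaf_node_iter()}
    missing = (present | absent) - tip_names
    if missing:
        raise KeyError(f"scored species not in tree: {sorted(missing)}")

    n_present, n_absent, scored_below = {}, {}, {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            n_present[id(node)] = int(name in present)
            n_absent[id(node)] = int(name in absent)
            scored_below[id(node)] = frozenset([name]) if name in present | absent else frozenset()
        else:
            kids = node.child_nodes()
            n_present[id(node)] = sum(n_present[id(k)] for k in kids)
            n_absent[id(node)] = sum(n_absent[id(k)] for k in kids)
            scored_below[id(node)] = frozenset().union(*(scored_below[id(k)] for k in kids))

    if gain == "root":
        gain_node = tree.seed_node
    else:
        gain_node = tree.seed_node
        while True:
            carriers = [k for k in gain_node.child_nodes() if n_present[id(k)] > 0]
            if len(carriers) == 1:
                gain_node = carriers[0]
            else:
                break

    losses = []

    def walk(node):
        for child in node.child_nodes():
            cid = id(child)
            if n_present[cid] == 0:
                if n_absent[cid] > 0:
                    losses.append(scored_below[cid])
                # clades with no scored tips are silent
            else:
                walk(child)

    walk(gain_node)
    return GainLossMap(paralog=paralog, gain_clade=scored_below[id(gain_node)],
                       loss_edges=losses)
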