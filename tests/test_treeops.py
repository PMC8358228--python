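from io import StringIO

import dendropy
import numpy as np
import pytest

from scrollsaw.evomodel import DistanceMatrix
from scrollsaw.io import parse_newick_dual_support
from scrollsaw.simulate import sim_tree
from scrollsaw.treeops import (_node_distance_table, assign_by_supported_clade,
                               dollo_map, mad_root, neighbor_joining,
                               tip_distances)


def _tree(newick):
    return parse_newick_dual_support(StringIO(newick))


def brute_force_mad(tree, grid=101):
    """Grid evaluation of the MAD score over every branch (test oracle)."""
    work = tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) == 2:
        work.deroot()
    nodes, index, dist = _node_distance_table(work)
    tips = [n for n in nodes if n.is_leaf()]
    tix = [index[id(t)] for t in tips]
    names = [t.taxon.label for t in tips]
    best = (np.inf, None, None)
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        L = node.edge.length or 0.0
        below = {l.taxon.label for l in node.leaf_iter()}
        for rho in np.linspace(0, 1, grid):
            devs = []
            for i in range(len(tips)):
                for j in range(i + 1, len(tips)):
                    dij = dist[tix[i], tix[j]]
                    if dij == 0:
                        continue
                    on_i, on_j = names[i] in below, names[j] in below
                    if on_i != on_j:
                        x = i if on_i else j
                        dxc = dist[tix[x], index[id(node)]]
                        r = abs(2 * (dxc + rho * L) / dij - 1)
                    else:
                        dxc = dist[tix[i], index[id(node)]]
                        dyc = dist[tix[j], index[id(node)]]
                        r = abs(dxc - dyc) / dij
                    devs.append(r * r)
            score = float(np.sqrt(np.mean(devs)))
            if score < best[0]:
                best = (score, frozenset(below), rho)
    return best


def brute_force_dollo(tree, present, absent, gain):
    """Minimal single-gain labelling by recursion over edge states (oracle)."""
    INF = 10**9

    def cost(node, state):
        if node.is_leaf():
            name = node.taxon.label
            if name in present:
                return 0 if state == 1 else INF
            if name in absent:
                return 0 if state == 0 else INF
            return 0
        total = 0
        for child in node.child_nodes():
            keep = cost(child, state)
            lose = cost(child, 0) + 1 if state == 1 else INF
            total += min(keep, lose)
        return total

    if gain == "root":
        return cost(tree.seed_node, 1)
    best = INF
    for node in tree.preorder_node_iter():
        tips_below = {l.taxon.label for l in node.leaf_iter()}
        if present <= tips_below:
            best = min(best, cost(node, 1))
    return best


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((a:0.1,b:0.2):0.5,(c:0.3,d:0.4)); internal branch 0.5
        ids = ["a", "b", "c", "d"]
        d = np.array([[0.0, 0.3, 0.9, 1.0],
                      [0.3, 0.0, 1.0, 1.1],
                      [0.9, 1.0, 0.0, 0.7],
                      [1.0, 1.1, 0.7, 0.0]])
        tree = neighbor_joining(DistanceMatrix(ids=ids, d=d))
        names, D = tip_distances(tree)
        ix = {n: i for i, n in enumerate(names)}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert D[ix[a], ix[b]] == pytest.approx(d[i, j], abs=1e-8)

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.5, 0.7], [0.5, 0.0, 0.8], [0.7, 0.8, 0.0]])
        tree = neighbor_joining(DistanceMatrix(ids=["a", "b", "c"], d=d))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((0.5 + 0.7 - 0.8) / 2, abs=1e-8)
        assert lengths["b"] == pytest.approx((0.5 + 0.8 - 0.7) / 2, abs=1e-8)
        assert lengths["c"] == pytest.approx((0.7 + 0.8 - 0.5) / 2, abs=1e-8)

    def test_undefined_entries_rejected(self):
        d = np.array([[0.0, np.nan, 0.7], [np.nan, 0.0, 0.8], [0.7, 0.8, 0.0]])
        with pytest.raises(ValueError, match="a"):
            neighbor_joining(DistanceMatrix(ids=["a", "b", "c"], d=d))


class TestMADRooting:
    def test_two_tip_midpoint(self):
        rooted, cand, _ = mad_root(_tree("(A:0.3,B:0.3);"))
        assert cand.mad_score == pytest.approx(0.0, abs=1e-12)
        lengths = sorted(l.edge.length for l in rooted.leaf_node_iter())
        assert lengths == pytest.approx([0.3, 0.3])

    def test_two_tip_asymmetric_lengths(self):
        rooted, cand, _ = mad_root(_tree("(A:0.1,B:0.5);"))
        lengths = {l.taxon.label: l.edge.length for l in rooted.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(0.3)
        assert lengths["B"] == pytest.approx(0.3)

    def test_clocklike_tree_recovers_true_root(self):
        tree = sim_tree(8, seed=5, clock=True, noise_sd=0.0)
        true_sides = [frozenset(l.taxon.label for l in c.leaf_iter())
                      for c in tree.seed_node.child_nodes()]
        all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        _, cand, _ = mad_root(tree)
        assert cand.mad_score == pytest.approx(0.0, abs=1e-9)
        assert cand.branch in true_sides or (all_tips - cand.branch) in true_sides

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_grid(self, seed):
        tree = sim_tree(8, seed=seed, clock=True, noise_sd=0.3)
        _, cand, _ = mad_root(tree)
        b_score, b_branch, b_rho = brute_force_mad(tree)
        all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        assert cand.branch in (b_branch, all_tips - b_branch) \
            or cand.mad_score <= b_score + 1e-9
        assert cand.mad_score == pytest.approx(b_score, abs=1e-3)

    def test_scale_invariance_of_root_position(self):
        tree = sim_tree(10, seed=2, clock=True, noise_sd=0.2)
        _, c1, _ = mad_root(tree)
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= 13.0
        _, c2, _ = mad_root(tree)
        assert c1.branch == c2.branch
        assert c1.rho == pytest.approx(c2.rho, abs=1e-9)
        assert c1.mad_score == pytest.approx(c2.mad_score, abs=1e-9)

    def test_rooted_tree_preserves_tip_distances(self):
        tree = sim_tree(9, seed=8, clock=True, noise_sd=0.2)
        names0, D0 = tip_distances(tree)
        rooted, _, _ = mad_root(tree)
        names1, D1 = tip_distances(rooted)
        ix = {n: i for i, n in enumerate(names1)}
        perm = [ix[n] for n in names0]
        assert np.allclose(D0, D1[np.ix_(perm, perm)], atol=1e-9)

    def test_multifurcating_input_accepted(self):
        rooted, cand, _ = mad_root(_tree("(A:0.1,B:0.1,C:0.1,D:0.5);"))
        assert np.isfinite(cand.mad_score)


class TestSupportedCladeAssignment:
    NEWICK = ("(((q:0.1,(r1:0.1,r2:0.1){s1}:0.1){s2}:0.1,r3:0.2){s3}:0.1,"
              "(x1:0.1,x2:0.1):0.1);")

    def _tree_with(self, s1="85/96", s2="85/96", s3="99/99"):
        nwk = self.NEWICK.format(s1=s1, s2=s2, s3=s3)
        return _tree(nwk)

    def test_minimal_supported_clade_wins(self):
        t = self._tree_with()
        refs = {"r1": "Arl8", "r2": "Arl8", "r3": "Arf1"}
        assert assign_by_supported_clade(t, "q", refs) == "Arl8"

    def test_threshold_is_inclusive_at_80(self):
        t = self._tree_with(s2="80/95")
        refs = {"r1": "Arl8", "r2": "Arl8"}
        assert assign_by_supported_clade(t, "q", refs) == "Arl8"

    def test_just_below_threshold_skipped(self):
        # 79/99 fails SH-aLRT>=80; next supported clade mixes labels -> None
        t = self._tree_with(s2="79/99", s3="99/99")
        refs = {"r1": "Arl8", "r2": "Arl8", "r3": "Arf1"}
        assert assign_by_supported_clade(t, "q", refs) is None

    def test_composite_label(self):
        t = self._tree_with(s2="79/99")
        refs = {"r1": "Arf1", "r2": "Arf1", "r3": "Arf6"}
        comp = {frozenset({"Arf1", "Arf6"}): "Arf1/6"}
        assert assign_by_supported_clade(t, "q", refs, composites=comp) == "Arf1/6"

    def test_missing_support_fails_conservatively(self):
        t = self._tree_with(s2="")
        refs = {"r1": "Arl8", "r2": "Arl8", "r3": "Arl8"}
        # s2 has no supports; s3 (99/99) still contains only Arl8 refs
        assert assign_by_supported_clade(t, "q", refs) == "Arl8"

    def test_unknown_query_rejected(self):
        t = self._tree_with()
        with pytest.raises(KeyError):
            assign_by_supported_clade(t, "nope", {"r1": "Arl8"})

    def test_invariant_to_rooting_outside_clade(self):
        refs = {"r1": "Arl8", "r2": "Arl8"}
        t1 = _tree("(((q:0.1,(r1:0.1,r2:0.1)85/96:0.1)90/97:0.1,x1:0.2)99/99:0.1,x2:0.3);")
        t2 = _tree("(x2:0.3,(x1:0.2,(q:0.1,(r1:0.1,r2:0.1)85/96:0.1)90/97:0.1)99/99:0.1);")
        assert assign_by_supported_clade(t1, "q", refs) == \
            assign_by_supported_clade(t2, "q", refs) == "Arl8"


class TestDollo:
    TREE = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"

    def test_no_absence_no_losses(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        m = dollo_map(t, {"A", "B", "C", "D"}, set(), gain="root")
        assert m.n_losses == 0

    def test_single_present_tip_from_root(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        m = dollo_map(t, {"A"}, {"B", "C", "D"}, gain="root")
        assert sorted(sorted(e) for e in m.loss_edges) == [["B"], ["C", "D"]]

    def test_alternating_pattern(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        m = dollo_map(t, {"A", "C"}, {"B", "D"}, gain="root")
        assert m.n_losses == 2

    def test_exhaustive_patterns_match_brute_force(self):
        t = _tree(self.TREE)
        tips = sorted(l.taxon.label for l in t.leaf_node_iter())
        for pattern in range(1, 2 ** 8):
            present = {tips[i] for i in range(8) if pattern >> i & 1}
            absent = set(tips) - present
            for gain in ("root", "mrca"):
                m = dollo_map(t, present, absent, gain=gain)
                expected = brute_force_dollo(t, present, absent, gain)
                assert m.n_losses == expected, (present, gain)

    def test_mrca_gain_never_costs_more_than_root_gain(self):
        t = _tree(self.TREE)
        tips = sorted(l.taxon.label for l in t.leaf_node_iter())
        rng = np.random.default_rng(4)
        for _ in range(30):
            present = {tip for tip in tips if rng.random() < 0.4} or {tips[0]}
            absent = set(tips) - present
            m_root = dollo_map(t, present, absent, gain="root")
            m_mrca = dollo_map(t, present, absent, gain="mrca")
            assert m_mrca.n_losses <= m_root.n_losses

    def test_unknown_tips_ignored(self):
        t = _tree(self.TREE)
        # C, D unscored (e.g. transcriptome-only): they neither trigger nor
        # block losses
        m = dollo_map(t, {"A", "E"}, {"B", "F", "G", "H"}, gain="root")
        m_pruned = dollo_map(_tree("((A:1,B:1):2,((E:1,F:1):1,(G:1,H:1):1):1);"),
                             {"A", "E"}, {"B", "F", "G", "H"}, gain="root")
        assert m.n_losses == m_pruned.n_losses

    def test_no_present_tips_rejected(self):
        t = _tree(self.TREE)
        with pytest.raises(ValueError):
            dollo_map(t, set(), {"A"}, gain="root")

    def test_loss_edges_within_gain_subtree(self):
        t = _tree(self.TREE)
        m = dollo_map(t, {"A", "B"}, {"C", "D"}, gain="mrca")
        for edge in m.loss_edges:
            assert edge <= m.gain_clade
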