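"""Parsimony mapping and ordered reconstruction against brute force."""

import itertools
import random

import pytest

from enamelevo.model import EnamelScoreTable
from enamelevo.parsimony import (
    branch_enamel_score,
    branch_scores,
    classify_origin,
    count_recovered_clades,
    map_lesion,
    sankoff_ordered,
)
from enamelevo.timetree import TimeTree, TreeError

from conftest import make_random_timetree


def exhaustive_ordered(tree, scores):
    """Minimal Wagner cost and MPR sets by enumerating every internal
    assignment (independent oracle, feasible for <= 6 tips)."""
    internals = [tree.label(nd) for nd in tree.tree.preorder_node_iter()
                 if not nd.is_leaf()]
    children = {tree.label(nd): [tree.label(c) for c in nd.child_nodes()]
                for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()}
    tipsets = {t: set(scores.states(t)) if t in scores else set(range(1, 6))
               for t in tree.taxa}
    best = None
    best_sets = {lab: set() for lab in internals}
    for assign in itertools.product(range(1, 6), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        cost = 0
        for lab in internals:
            for c in children[lab]:
                if c in amap:
                    cost += abs(amap[lab] - amap[c])
                else:
                    cost += min(abs(amap[lab] - s) for s in tipsets[c])
        if best is None or cost < best:
            best = cost
            best_sets = {lab: {amap[lab]} for lab in internals}
        elif cost == best:
            for lab in internals:
                best_sets[lab].add(amap[lab])
    return best, best_sets


def consistent_origins(tree, origins, present, absent):
    covered = set()
    for o in origins:
        leaves = tree.leaf_set(o)
        if leaves & absent:
            return False
        covered |= leaves
    return present <= covered


def minimal_origin_count(tree, present, absent):
    branches = tree.branches()
    for k in range(1, len(branches) + 1):
        for combo in itertools.combinations(branches, k):
            if consistent_origins(tree, set(combo), present, absent):
                return k
    raise AssertionError("no consistent mapping")


class TestMapLesion:
    def test_shared_lesion_maps_to_stem(self, species_tree_93):
        tree = species_tree_93
        presence = {t: "absent" for t in tree.taxa}
        presence["Kogia_breviceps"] = presence["Kogia_sima"] = "present"
        for method in ("ACCTRAN", "DELTRAN"):
            origins = map_lesion(tree, presence, method)
            assert len(origins) == 1
            assert origins[0].branch == tree.mrca(["Kogia_breviceps", "Kogia_sima"])
            assert classify_origin(origins[0], tree) == "synapomorphic"

    def test_single_tip_maps_to_terminal_branch(self, species_tree_93):
        tree = species_tree_93
        presence = {t: "absent" for t in tree.taxa}
        presence["Ziphius_cavirostris"] = "present"
        origins = map_lesion(tree, presence, "DELTRAN")
        assert [o.branch for o in origins] == ["Ziphius_cavirostris"]
        assert classify_origin(origins[0], tree) == "autapomorphic"

    def test_unlisted_taxa_rejected(self, species_tree_93):
        with pytest.raises(TreeError, match="not on tree"):
            map_lesion(species_tree_93, {"NotATaxon": "present"}, "DELTRAN")

    def test_brute_force_oracle(self, rnd):
        """Both resolutions are minimal, consistent, and respect their
        rootward/tipward placement conventions (irreversible character)."""
        checked = 0
        while checked < 60:
            tree = make_random_timetree(rnd, rnd.randint(3, 5))
            states = {t: rnd.choice(["present", "absent", "unknown"])
                      for t in tree.taxa}
            present = {t for t, s in states.items() if s == "present"}
            absent = {t for t, s in states.items() if s == "absent"}
            if not present:
                continue
            checked += 1
            k_min = minimal_origin_count(tree, present, absent)
            for method in ("ACCTRAN", "DELTRAN"):
                origins = map_lesion(tree, states, method)
                branches = {o.branch for o in origins}
                assert consistent_origins(tree, branches, present, absent)
                assert len(branches) == k_min
                for o in origins:
                    if method == "DELTRAN":
                        # delayed: origin sits on the bearers' stem
                        assert o.branch == tree.mrca(set(o.bearers))
                    else:
                        # accelerated: pushing further rootward would
                        # cover an intact taxon (or cross the root)
                        parent = tree.node(o.branch).parent_node
                        assert parent is tree.root or \
                            tree.leaf_set(parent) & absent

    def test_no_bearers_yields_no_origins(self, rnd):
        tree = make_random_timetree(rnd, 4)
        assert map_lesion(tree, {t: "absent" for t in tree.taxa}) == []


class TestSankoff:
    def test_identical_cherry(self):
        tree = TimeTree.from_newick("(a:1,b:1);")
        rec = sankoff_ordered(tree, EnamelScoreTable({"a": [5], "b": [5]}))
        assert rec.cost == 0
        root = tree.label(tree.root)
        assert rec.mpr[root] == frozenset({5})
        assert rec.value[root] == 5

    def test_polymorphic_cherry_tip_values(self):
        tree = TimeTree.from_newick("(a:1,b:1);")
        rec = sankoff_ordered(tree, EnamelScoreTable({"a": [1], "b": [1, 2]}))
        assert rec.value["a"] == 1.0
        assert rec.value["b"] == 1.5
        assert rec.cost == 0  # ancestor state 1 reaches both tip sets

    def test_exhaustive_oracle(self, rnd):
        for _ in range(40):
            tree = make_random_timetree(rnd, rnd.randint(3, 6))
            raw = {}
            for t in tree.taxa:
                if rnd.random() < 0.25:
                    a = rnd.randint(1, 4)
                    raw[t] = [a, a + 1]
                else:
                    raw[t] = [rnd.randint(1, 5)]
            table = EnamelScoreTable(raw)
            rec = sankoff_ordered(tree, table, "MPR")
            cost, mpr = exhaustive_ordered(tree, table)
            assert rec.cost == cost
            for lab, states in mpr.items():
                assert set(rec.mpr[lab]) == states, lab

    def test_resolutions_are_most_parsimonious(self, rnd):
        """ACCTRAN/DELTRAN assignments realize the Sankoff minimum."""
        for _ in range(25):
            tree = make_random_timetree(rnd, rnd.randint(3, 6))
            table = EnamelScoreTable({t: [rnd.randint(1, 5)] for t in tree.taxa})
            target = sankoff_ordered(tree, table, "MPR").cost
            for res in ("ACCTRAN", "DELTRAN"):
                rec = sankoff_ordered(tree, table, res)
                cost = 0
                for nd in tree.tree.preorder_node_iter():
                    vp = rec.value[tree.label(nd)]
                    for c in nd.child_nodes():
                        lc = tree.label(c)
                        if c.is_leaf():
                            cost += min(abs(vp - s) for s in table.states(lc))
                        else:
                            cost += abs(vp - rec.value[lc])
                assert cost == pytest.approx(target), res

    def test_cost_invariant_to_rerooting(self, rnd):
        def as_timetree(dtree):
            # topology only: re-derive valid ages from node depth
            def emit(node):
                if node.is_leaf():
                    return node.taxon.label, 0.0
                parts = [emit(c) for c in node.child_nodes()]
                age = max(a for _, a in parts) + 1.0
                body = ",".join(f"{s}:{age - a}" for s, a in parts)
                return f"({body})", age
            s, _ = emit(dtree.seed_node)
            return TimeTree.from_newick(s + ";")

        for _ in range(10):
            tree = make_random_timetree(rnd, 6)
            table = EnamelScoreTable({t: [rnd.randint(1, 5)] for t in tree.taxa})
            base = sankoff_ordered(tree, table).cost
            d = tree.tree.clone(depth=1)
            edges = [e for e in d.preorder_edge_iter()
                     if e.head_node is not d.seed_node and e.length]
            d.reroot_at_edge(edges[rnd.randrange(len(edges))],
                             update_bipartitions=False)
            d.suppress_unifurcations()
            assert sankoff_ordered(as_timetree(d), table).cost == base

    def test_empty_table_rejected(self, rnd):
        tree = make_random_timetree(rnd, 4)
        with pytest.raises(ValueError, match="empty"):
            sankoff_ordered(tree, EnamelScoreTable({}))


class TestBranchScores:
    @pytest.mark.parametrize("parent,child,expected", [
        (3.0, 3.0, 3.0),    # equal endpoints keep their score
        (4.0, 2.0, 3.0),    # unequal endpoints take the mean
        (1.0, 1.5, 1.25),   # fixed -> polymorphic tip
        (1.5, 1.5, 1.5),    # polymorphic -> polymorphic
    ])
    def test_published_rules(self, parent, child, expected):
        assert branch_enamel_score(parent, child) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            branch_enamel_score(0.5, 3.0)

    def test_scores_bounded_on_random_trees(self, rnd):
        for _ in range(10):
            tree = make_random_timetree(rnd, 7)
            table = EnamelScoreTable({t: [rnd.randint(1, 5)] for t in tree.taxa})
            rec = sankoff_ordered(tree, table, "DELTRAN")
            for score in branch_scores(tree, rec).values():
                assert 1.0 <= score <= 5.0


class TestCladeRecovery:
    def test_self_recovery(self, species_tree_93, taxon_table):
        tree = species_tree_93
        fams = taxon_table.groupby("family")["taxon"].apply(list)
        clades = [set(m) for m in fams if len(m) >= 2]
        recovered, evaluated = count_recovered_clades(tree.tree, clades)
        assert recovered == evaluated == len(clades)

    def test_one_misplaced_tip_breaks_one_clade(self):
        true = TimeTree.from_newick("(((a:1,b:1):1,(c:1,d:1):1):1,e:3);")
        broken = TimeTree.from_newick("(((a:1,c:1):1,(b:1,d:1):1):1,e:3);")
        clades = [{"a", "b"}, {"c", "d"}, {"a", "b", "c", "d"}]
        assert count_recovered_clades(true.tree, clades) == (3, 3)
        assert count_recovered_clades(broken.tree, clades) == (1, 3)

    def test_single_sampled_member_excluded(self):
        tree = TimeTree.from_newick("((a:1,b:1):1,c:2);")
        recovered, evaluated = count_recovered_clades(
            tree.tree, [{"a", "b"}, {"c", "zz"}])
        assert (recovered, evaluated) == (1, 1)
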