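"""Parsimony mapping of lesions and ordered reconstruction of enamel
complexity.

Lesions are optimized as irreversible binary characters: once a gene is
inactivated along a lineage it cannot regain function, so an origin may
only be placed on a branch whose descendants include no taxon observed
with the intact state.  ACCTRAN pushes each origin as far rootward as
that constraint allows; DELTRAN delays it to the stem of the observed
bearers.  Both resolutions imply the same number of origins.

Enamel complexity is an ordered (Wagner) character on states 1..5 with
linear cost |i - j|, solved by Sankoff dynamic programming.  MPR state
sets are computed exactly; equivocal nodes are valued at the mean of
their MPR set, and polymorphic tips at the mean of their two categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .model import EnamelScoreTable
from .timetree import TimeTree, TreeError

__all__ = [
    "map_lesion",
    "classify_origin",
    "OriginAssignment",
    "sankoff_ordered",
    "Reconstruction",
    "branch_enamel_score",
    "branch_scores",
    "count_recovered_clades",
]

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"

_INF = math.inf


@dataclass(frozen=True)
class OriginAssignment:
    """One inferred lesion origin: the branch and the bearers below it."""

    branch: str
    bearers: tuple[str, ...]

    @property
    def synapomorphic(self) -> bool:
        return len(self.bearers) >= 2


def map_lesion(tree: TimeTree, presence: Mapping[str, str],
               method: str = "DELTRAN") -> list[OriginAssignment]:
    """Place the origins of an irreversible binary lesion character.

    ``presence`` maps taxa to "present"/"absent"/"unknown"; taxa not
    listed default to unknown (wildcards).  Returns one assignment per
    origin branch (child-node labels).
    """
    method = method.upper()
    if method not in ("ACCTRAN", "DELTRAN"):
        raise ValueError(f"method must be ACCTRAN or DELTRAN, not {method!r}")
    bad = set(presence) - set(tree.taxa)
    if bad:
        raise TreeError(f"presence labels not on tree: {sorted(bad)}")
    present = {t for t, s in presence.items() if s == PRESENT}
    absent = {t for t, s in presence.items() if s == ABSENT}
    if not present:
        return []

    root = tree.root
    tainted: dict[dendropy.Node, bool] = {}
    has_present: dict[dendropy.Node, bool] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            name = tree.label(node)
            tainted[node] = name in absent
            has_present[node] = name in present
        else:
            kids = node.child_nodes()
            tainted[node] = any(tainted[c] for c in kids)
            has_present[node] = any(has_present[c] for c in kids)

    # maximal absent-free subtrees containing at least one bearer
    def clean_heads(node) -> list[dendropy.Node]:
        if not tainted[node]:
            return [node] if has_present[node] else []
        heads = []
        for c in node.child_nodes():
            heads.extend(clean_heads(c))
        return heads

    assignments: list[OriginAssignment] = []
    for head in clean_heads(root):
        bearers = tuple(sorted(tree.leaf_set(head) & present))
        if method == "DELTRAN":
            origin_node = tree.node(tree.mrca(bearers))
        else:
            origin_node = head
        if origin_node is root:
            # never place an origin on the root branch: push one level down
            for c in origin_node.child_nodes():
                sub = tuple(sorted(tree.leaf_set(c) & present))
                if sub:
                    target = c if method == "ACCTRAN" else tree.node(tree.mrca(sub))
                    assignments.append(
                        OriginAssignment(tree.label(target), sub)
                    )
            continue
        assignments.append(OriginAssignment(tree.label(origin_node), bearers))
    return assignments


def classify_origin(origin: OriginAssignment, tree: TimeTree) -> str:
    """'synapomorphic' if the origin branch subtends >=2 sampled bearers."""
    bearers = set(origin.bearers) & tree.leaf_set(origin.branch)
    return "synapomorphic" if len(bearers) >= 2 else "autapomorphic"


# -- ordered (Wagner) reconstruction -----------------------------------


@dataclass
class Reconstruction:
    """Result of an ordered-character ancestral reconstruction."""

    cost: float
    mpr: dict[str, frozenset[int]]          # node label -> MPR state set
    value: dict[str, float]                 # node label -> point value
    resolution: str                         # MPR | ACCTRAN | DELTRAN


def sankoff_ordered(tree: TimeTree, scores: EnamelScoreTable,
                    resolution: str = "MPR",
                    states: Iterable[int] = (1, 2, 3, 4, 5)) -> Reconstruction:
    """Sankoff reconstruction of an ordered character with cost |i - j|.

    Tips without a score are wildcards.  ``resolution`` selects how
    equivocal nodes are valued: MPR keeps the full state set (value =
    mean of the set's extremes), ACCTRAN/DELTRAN produce a unique state
    per internal node (changes accelerated rootward / delayed tipward;
    remaining ties resolved toward the higher, ancestral-complexity
    state).
    """
    resolution = resolution.upper()
    if resolution not in ("MPR", "ACCTRAN", "DELTRAN"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if len(scores) == 0:
        raise ValueError("empty score table")
    states = sorted(states)
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    cost = np.abs(np.subtract.outer(np.array(states), np.array(states))).astype(float)

    nodes = list(tree.tree.postorder_node_iter())
    down: dict[dendropy.Node, np.ndarray] = {}
    # down[v][s]: min cost of subtree at v given v has state s
    for node in nodes:
        if node.is_leaf():
            name = tree.label(node)
            vec = np.full(k, _INF)
            if name in scores:
                for s in scores.states(name):
                    vec[idx[s]] = 0.0
            else:
                vec[:] = 0.0
            down[node] = vec
        else:
            vec = np.zeros(k)
            for c in node.child_nodes():
                vec += (cost + down[c][None, :]).min(axis=1)
            down[node] = vec

    root = tree.root
    total = float(down[root].min())

    # up[v][s]: min cost of everything outside v's subtree given v state s
    up: dict[dendropy.Node, np.ndarray] = {root: np.zeros(k)}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        kid_contrib = {
            c: (cost + down[c][None, :]).min(axis=1) for c in node.child_nodes()
        }
        total_contrib = sum(kid_contrib.values())
        base = up[node] + total_contrib
        for c in node.child_nodes():
            parent_given = base - kid_contrib[c]  # cost at parent excluding c
            up[c] = (cost + parent_given[:, None]).min(axis=0)

    mpr: dict[str, frozenset[int]] = {}
    value: dict[str, float] = {}
    for node in nodes:
        name = tree.label(node)
        if node.is_leaf() and name in scores:
            # scored tips keep their observed state set; a polymorphic
            # tip is valued at the mean of its two categories
            sset = scores.states(name)
        else:
            final = down[node] + up[node]
            sset = frozenset(states[i] for i in np.flatnonzero(final <= total + 1e-9))
        mpr[name] = sset
        value[name] = (min(sset) + max(sset)) / 2

    if resolution != "MPR":
        chosen: dict[dendropy.Node, int] = {}
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node is root:
                candidates = [s for s in states if down[root][idx[s]] <= total + 1e-9]
                pick = max(candidates)
            else:
                t = chosen[node.parent_node]
                cond = down[node] + cost[idx[t]]
                best = cond.min()
                candidates = [states[i] for i in np.flatnonzero(cond <= best + 1e-9)]
                if resolution == "DELTRAN":
                    d = min(abs(s - t) for s in candidates)
                else:
                    d = max(abs(s - t) for s in candidates)
                pool = [s for s in candidates if abs(s - t) == d]
                pick = max(pool)
            chosen[node] = pick
            name = tree.label(node)
            mpr[name] = frozenset({pick})
            value[name] = float(pick)

    return Reconstruction(cost=total, mpr=mpr, value=value, resolution=resolution)


def branch_enamel_score(parent_value: float, child_value: float) -> float:
    """A branch is scored by the mean of its endpoint values (equal
    endpoints keep their value; polymorphic/equivocal endpoints are
    collapsed to their own means first)."""
    for v in (parent_value, child_value):
        if not 1.0 <= v <= 5.0:
            raise ValueError(f"endpoint value {v} outside [1, 5]")
    return (parent_value + child_value) / 2


def branch_scores(tree: TimeTree, rec: Reconstruction) -> dict[str, float]:
    """Per-branch enamel scores from a reconstruction (branch = child label)."""
    out = {}
    for branch in tree.branches():
        parent = tree.parent_label(branch)
        out[branch] = branch_enamel_score(rec.value[parent], rec.value[branch])
    return out


# -- gene-tree clade recovery ------------------------------------------


def count_recovered_clades(gene_tree, reference_clades: list[Iterable[str]]
                           ) -> tuple[int, int]:
    """Count reference clades recovered as monophyletic in a gene tree.

    Clades with fewer than two members sampled in the gene tree are
    excluded from the denominator.  Returns (recovered, evaluated).
    Monophyly is assessed on the bipartitions of the (unrooted) gene
    tree.
    """
    if isinstance(gene_tree, TimeTree):
        tree = gene_tree.tree
    elif isinstance(gene_tree, dendropy.Tree):
        tree = gene_tree
    else:
        tree = dendropy.Tree.get(data=str(gene_tree), schema="newick",
                                 preserve_underscores=True)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    leafsets: dict[dendropy.Node, frozenset[str]] = {}
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([node.taxon.label])
        else:
            leafsets[node] = frozenset().union(*(leafsets[c] for c in node.child_nodes()))
            splits.add(leafsets[node])
            splits.add(frozenset(tips - leafsets[node]))
    recovered = evaluated = 0
    for clade in reference_clades:
        members = frozenset(clade) & tips
        if len(members) < 2:
            continue
        evaluated += 1
        if members == tips or members in splits:
            recovered += 1
    return recovered, evaluated
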