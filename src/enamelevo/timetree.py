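"""Rooted species tree with node ages in millions of years (MYR).

Branch lengths of the input Newick are interpreted as durations in MYR.
Node ages are derived bottom-up (tips at age 0 unless given); a branch's
duration is parent age minus child age and must be positive.  Every
branch is identified by the label of its child node; unlabeled internal
nodes get a deterministic label derived from their smallest descendant
tip name.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

__all__ = ["TimeTree", "TreeError"]

_AGE_TOL = 1e-6


class TreeError(ValueError):
    pass


class TimeTree:
    def __init__(self, tree: dendropy.Tree, tip_ages: dict[str, float] | None = None):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self._tree = tree
        self._tip_ages = dict(tip_ages or {})
        self._index()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, tip_ages: dict[str, float] | None = None) -> "TimeTree":
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        return cls(tree, tip_ages)

    @classmethod
    def from_path(cls, path, tip_ages: dict[str, float] | None = None) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), tip_ages)

    def _index(self):
        tree = self._tree
        self._label: dict[dendropy.Node, str] = {}
        self._leafset: dict[dendropy.Node, frozenset[str]] = {}
        used: set[str] = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("leaf without a taxon label")
                name = node.taxon.label
                self._leafset[node] = frozenset([name])
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.child_nodes())
                )
                name = None
                if node.taxon is not None and node.taxon.label:
                    name = node.taxon.label
                elif node.label:
                    name = node.label
                if not name or name in used:
                    # smallest descendant tip + clade size: unique and stable
                    name = f"mrca_{min(self._leafset[node])}_{len(self._leafset[node])}"
            if name in used:
                raise TreeError(f"duplicate node label {name!r}")
            used.add(name)
            self._label[node] = name
        self._node_of = {lbl: nd for nd, lbl in self._label.items()}
        # ages bottom-up; durations are the Newick branch lengths
        self._age: dict[dendropy.Node, float] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._age[node] = float(self._tip_ages.get(self._label[node], 0.0))
            else:
                ages = []
                for c in node.child_nodes():
                    bl = c.edge.length
                    if bl is None:
                        raise TreeError(f"branch above {self._label[c]!r} has no length")
                    if bl <= 0:
                        raise TreeError(
                            f"non-positive duration {bl} above {self._label[c]!r} "
                            "(child at least as old as parent)"
                        )
                    ages.append(self._age[c] + float(bl))
                if max(ages) - min(ages) > _AGE_TOL:
                    raise TreeError(
                        f"inconsistent node age at {self._label[node]!r}: "
                        f"children imply ages {ages}"
                    )
                self._age[node] = ages[0]

    # -- queries ------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def taxa(self) -> list[str]:
        return sorted(self._leafset[self.root])

    def label(self, node: dendropy.Node) -> str:
        return self._label[node]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._node_of[label]
        except KeyError:
            raise TreeError(f"no node labeled {label!r}") from None

    def leaf_set(self, node_or_label) -> frozenset[str]:
        node = node_or_label if isinstance(node_or_label, dendropy.Node) else self.node(node_or_label)
        return self._leafset[node]

    def age(self, node_or_label) -> float:
        node = node_or_label if isinstance(node_or_label, dendropy.Node) else self.node(node_or_label)
        return self._age[node]

    def duration(self, branch: str) -> float:
        """Duration in MYR of the branch above the node labeled `branch`."""
        node = self.node(branch)
        if node is self.root:
            raise TreeError("the root has no branch above it")
        return float(node.edge.length)

    def branches(self) -> list[str]:
        """Child-node labels of all branches (root excluded), postorder."""
        return [
            self._label[n]
            for n in self._tree.postorder_node_iter()
            if n is not self.root
        ]

    def parent_label(self, branch: str) -> str:
        node = self.node(branch)
        if node is self.root:
            raise TreeError("the root has no parent")
        return self._label[node.parent_node]

    def mrca(self, taxa: Iterable[str]) -> str:
        want = set(taxa)
        missing = want - set(self._leafset[self.root])
        if missing:
            raise TreeError(f"taxa not on tree: {sorted(missing)}")
        best = None
        for node in self._tree.postorder_node_iter():
            if want <= self._leafset[node]:
                best = node
                break
        return self._label[best]

    def children(self, label: str) -> list[str]:
        return [self._label[c] for c in self.node(label).child_nodes()]

    def as_newick(self, annotations: dict[str, str] | None = None) -> str:
        """Newick text; optional per-branch comment annotations keyed by branch id."""
        tree = self._tree.clone(depth=1)
        out = tree.as_string(schema="newick", suppress_rooting=True).strip()
        if annotations:
            for branch, note in annotations.items():
                out = out.replace(f"{branch}:", f"{branch}[&{note}]:")
        return out

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")
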