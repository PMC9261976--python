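"""Rooted species tree with labeled internal nodes.

The phylostratigraphic classifier only ever needs three things from the
phylogeny: the set of leaves under each named clade, the MRCA of an
arbitrary leaf subset, and the identity of the root.  ``SpeciesTree``
wraps a dendropy tree and precomputes these so downstream code never
touches dendropy objects directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy

__all__ = ["SpeciesTree", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees (duplicate/missing labels, unknown species)."""


@dataclass
class SpeciesTree:
    """Rooted phylogeny with uniquely labeled internal nodes.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.  Every internal node must carry a
        unique label; leaf labels are the species IDs.
    """

    tree: dendropy.Tree
    _leafsets: dict[str, frozenset[str]] = field(init=False, repr=False)
    _children: dict[str, list[str]] = field(init=False, repr=False)
    root_label: str = field(init=False)
    leaves: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self._leafsets = {}
        self._children = {}
        seen: set[str] = set()
        leaves: list[str] = []

        def walk(node) -> frozenset[str]:
            label = _node_label(node)
            if label is None:
                raise TreeError("every node (internal included) must be labeled")
            if label in seen:
                raise TreeError(f"duplicate node label: {label!r}")
            seen.add(label)
            kids = node.child_nodes()
            if not kids:
                leaves.append(label)
                ls = frozenset([label])
            else:
                self._children[label] = []
                parts: set[str] = set()
                for child in kids:
                    cl = walk(child)
                    self._children[label].append(_node_label(child))
                    parts |= cl
                ls = frozenset(parts)
            self._leafsets[label] = ls
            return ls

        root = self.tree.seed_node
        walk(root)
        self.root_label = _node_label(root)
        self.leaves = tuple(leaves)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "SpeciesTree":
        """Parse a newick string or file path (internal node labels required)."""
        kwargs = dict(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        try:
            if "(" in source:
                t = dendropy.Tree.get(data=source, **kwargs)
            else:
                t = dendropy.Tree.get(path=source, **kwargs)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse newick: {exc}") from exc
        return cls(t)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    # -- queries ---------------------------------------------------------
    @property
    def node_labels(self) -> frozenset[str]:
        return frozenset(self._leafsets)

    @property
    def internal_labels(self) -> frozenset[str]:
        return frozenset(self._children)

    def leaf_set(self, label: str) -> frozenset[str]:
        """Leaves descending from (and including) the node ``label``."""
        try:
            return self._leafsets[label]
        except KeyError:
            raise TreeError(f"unknown node label: {label!r}") from None

    def children(self, label: str) -> list[str]:
        return list(self._children.get(label, []))

    def mrca(self, species: Iterable[str]) -> str:
        """Label of the most recent common ancestor of a nonempty leaf subset."""
        target = frozenset(species)
        if not target:
            raise TreeError("MRCA of an empty leaf set is undefined")
        unknown = target - self._leafsets[self.root_label]
        if unknown:
            raise TreeError(f"species not in tree: {sorted(unknown)}")
        node = self.root_label
        while True:
            for child in self._children.get(node, ()):  # leaves have no children
                if target <= self._leafsets[child]:
                    node = child
                    break
            else:
                return node

    def is_leaf(self, label: str) -> bool:
        return label in self._leafsets and label not in self._children


def _node_label(node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None
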