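"""NCBI-taxdump-style taxonomy trees and the ancestry queries used by read classifiers.

The classifiers in this package place a matched taxon into a coarse clade
("category") either by depth from the root (the ancestor at a fixed level,
root = level 1) or by rank label (the nearest ancestor whose rank is, e.g.,
``"genus"``).  Taxa whose names indicate that they are not real organisms
("uncultured organism", "environmental samples", ...) are flagged as
taxonomically unclassifiable so that reads matching only such records can be
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "DEFAULT_UNCLASSIFIABLE_PATTERNS",
    "load_taxdump",
    "write_taxdump",
]

#: Case-insensitive substrings marking a taxon (or any of its ancestors) as
#: taxonomically unclassifiable.
DEFAULT_UNCLASSIFIABLE_PATTERNS: tuple[str, ...] = (
    "uncultured",
    "unclassified",
    "unidentified",
    "environmental sample",
    "metagenome",
)


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy (orphan node, cycle, missing root...)."""


@dataclass(frozen=True)
class TaxonNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str = ""


@dataclass
class TaxonomyTree:
    """Rooted taxonomy; the root's parent is itself (taxdump convention)."""

    nodes: dict[int, TaxonNode]
    root_id: int
    _depths: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"node {node.tax_id} has parent {node.parent_id} "
                    "which is absent from the taxonomy"
                )
        if self.root_id not in self.nodes:
            raise TaxonomyError(f"root id {self.root_id} not among nodes")
        root = self.nodes[self.root_id]
        if root.parent_id != root.tax_id:
            raise TaxonomyError("root node must be its own parent")
        # Depth computation doubles as cycle detection.
        for tax_id in self.nodes:
            self.depth(tax_id)

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return self.nodes == other.nodes and self.root_id == other.root_id

    def _require(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise KeyError(f"unknown tax_id {tax_id}") from None

    def depth(self, tax_id: int) -> int:
        """Depth from root; the root has depth 1."""
        self._require(tax_id)
        path = []
        cur = tax_id
        while cur not in self._depths:
            path.append(cur)
            node = self.nodes[cur]
            if node.parent_id == cur:  # root
                self._depths[cur] = 1
                break
            if len(path) > len(self.nodes):
                raise TaxonomyError(f"cyclic parent chain through node {tax_id}")
            cur = node.parent_id
        for tax in reversed(path):
            parent = self.nodes[tax].parent_id
            if tax not in self._depths:
                self._depths[tax] = self._depths[parent] + 1
        return self._depths[tax_id]

    def path_from_root(self, tax_id: int) -> list[int]:
        """Taxon ids from the root down to (and including) ``tax_id``."""
        self._require(tax_id)
        path = [tax_id]
        cur = tax_id
        while self.nodes[cur].parent_id != cur:
            cur = self.nodes[cur].parent_id
            path.append(cur)
            if len(path) > len(self.nodes):
                raise TaxonomyError(f"cyclic parent chain through node {tax_id}")
        path.reverse()
        return path

    def ancestor_at_level(self, tax_id: int, level: int) -> int:
        """Ancestor of ``tax_id`` at the given depth from the root (root = 1).

        A node shallower than ``level`` maps to itself, so coarse taxa remain
        usable as categories.  Idempotent at a fixed level.
        """
        if level < 1:
            raise ValueError(f"level must be >= 1, got {level}")
        path = self.path_from_root(tax_id)
        if len(path) <= level:
            return tax_id
        return path[level - 1]

    def rank_ancestor(self, tax_id: int, rank: str) -> int | None:
        """Nearest ancestor (including self) with the given rank label, or None."""
        cur = self._require(tax_id).tax_id
        seen = 0
        while True:
            node = self.nodes[cur]
            if node.rank == rank:
                return cur
            if node.parent_id == cur:
                return None
            cur = node.parent_id
            seen += 1
            if seen > len(self.nodes):
                raise TaxonomyError(f"cyclic parent chain through node {tax_id}")

    def is_unclassifiable(
        self,
        tax_id: int,
        patterns: Iterable[str] = DEFAULT_UNCLASSIFIABLE_PATTERNS,
    ) -> bool:
        """True if the node's name, or any ancestor's, matches a pattern.

        Matching is case-insensitive substring containment; the default
        pattern set covers the usual placeholder taxa of public databases
        (uncultured/unclassified/unidentified organisms, environmental
        samples, metagenomes).
        """
        pats = [p.lower() for p in patterns]
        for anc in self.path_from_root(tax_id):
            name = self.nodes[anc].name.lower()
            if any(p in name for p in pats):
                return True
        return False

    def descends_from(self, tax_id: int, ancestor_id: int) -> bool:
        """True if ``tax_id`` equals or lies below ``ancestor_id``."""
        return ancestor_id in self.path_from_root(tax_id)


def _parse_dmp_line(line: str) -> list[str]:
    # taxdump dialect: fields separated by "\t|\t", record terminated "\t|".
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load a taxonomy from taxdump-dialect ``nodes.dmp``/``names.dmp`` files.

    Only "scientific name" entries populate node names.  Raises
    :class:`TaxonomyError` for orphan nodes or cyclic parent chains.
    """
    names: dict[int, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            tax_id, name = int(fields[0]), fields[1]
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name":
                names[tax_id] = name

    nodes: dict[int, TaxonNode] = {}
    root_id: int | None = None
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            tax_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes[tax_id] = TaxonNode(tax_id, parent_id, rank, names.get(tax_id, ""))
            if tax_id == parent_id:
                root_id = tax_id
    if root_id is None:
        raise TaxonomyError("no root node (self-parented) found in nodes file")
    return TaxonomyTree(nodes=nodes, root_id=root_id)


def write_taxdump(
    tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path
) -> None:
    """Write a taxonomy in the taxdump dialect (inverse of :func:`load_taxdump`)."""
    with open(nodes_path, "w") as fh:
        for node in sorted(tree.nodes.values(), key=lambda n: n.tax_id):
            fh.write(f"{node.tax_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|\n")
    with open(names_path, "w") as fh:
        for node in sorted(tree.nodes.values(), key=lambda n: n.tax_id):
            fh.write(f"{node.tax_id}\t|\t{node.name}\t|\t\t|\tscientific name\t|\n")
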