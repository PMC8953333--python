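"""Bacterial taxonomy trees and the Kraken2 report dialect.

A Kraken2 report is a tab-separated table with one row per taxon:

    percent  clade_reads  direct_reads  rank_code  taxid  name

where ``name`` is indented by two spaces per level of taxonomic depth and
``rank_code`` is one of U/R/D/K/P/C/O/F/G/S (optionally suffixed, e.g.
``S1`` for a strain below species).  Only the *direct* read counts
(column 3) are kept as abundances; clade-level rollups are recomputed
from the tree when writing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional

__all__ = [
    "RANKS",
    "TaxonNode",
    "TaxonomyTree",
    "Kraken2ParseError",
    "read_kraken2_report",
    "write_kraken2_report",
]

#: Canonical rank order, coarse to fine.  "unranked" sorts last so that the
#: parent-rank invariant (child never coarser than parent) stays checkable.
RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
    "unranked",
)

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

# Kraken2 single-letter rank codes.  'D' (domain) and 'K' (kingdom) both map
# to kingdom; 'U' (unclassified) and 'R' (root) carry no taxonomic rank.
_RANK_CODES = {
    "U": "unranked",
    "R": "unranked",
    "D": "kingdom",
    "K": "kingdom",
    "P": "phylum",
    "C": "class",
    "O": "order",
    "F": "family",
    "G": "genus",
    "S": "species",
}

_RANK_TO_CODE = {
    "kingdom": "D",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
    "strain": "S1",
    "unranked": "R",
}


def rank_from_code(code: str) -> str:
    """Map a Kraken2 rank code (possibly suffixed, e.g. ``S1``) to a rank name."""
    if code in _RANK_CODES:
        return _RANK_CODES[code]
    base, suffix = code[0], code[1:]
    if suffix.isdigit():
        # Suffixed sub-levels: anything below species collapses to "strain",
        # suffixes of other codes have no named rank.
        if base == "S":
            return "strain"
        return "unranked"
    raise Kraken2ParseError(f"unknown rank code {code!r}")


class Kraken2ParseError(ValueError):
    """Raised when a Kraken2 report cannot be parsed."""


@dataclass
class TaxonNode:
    taxid: int
    name: str
    rank: str
    parent: Optional[int] = None
    children: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rank not in _RANK_INDEX:
            raise ValueError(f"unknown rank {self.rank!r} for taxid {self.taxid}")


class TaxonomyTree:
    """A rooted forest of :class:`TaxonNode` keyed by taxid."""

    def __init__(self) -> None:
        self.nodes: Dict[int, TaxonNode] = {}
        self.roots: List[int] = []

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self.nodes.values())

    def add_node(self, taxid: int, name: str, rank: str, parent: Optional[int] = None) -> TaxonNode:
        if taxid in self.nodes:
            raise ValueError(f"duplicate taxid {taxid}")
        if parent is not None:
            pnode = self.nodes[parent]
            if _RANK_INDEX[rank] < _RANK_INDEX[pnode.rank] and rank != "unranked" and pnode.rank != "unranked":
                raise ValueError(
                    f"taxid {taxid} has rank {rank!r} coarser than its parent's {pnode.rank!r}"
                )
        node = TaxonNode(taxid=taxid, name=name, rank=rank, parent=parent)
        self.nodes[taxid] = node
        if parent is None:
            self.roots.append(taxid)
        else:
            self.nodes[parent].children.append(taxid)
        return node

    def parent(self, taxid: int) -> Optional[int]:
        return self.nodes[taxid].parent

    def ancestors(self, taxid: int) -> Iterator[int]:
        """Yield ancestors from the immediate parent up to the root."""
        p = self.nodes[taxid].parent
        while p is not None:
            yield p
            p = self.nodes[p].parent

    def descendants(self, taxid: int) -> Iterator[int]:
        """Yield all strict descendants in depth-first preorder."""
        stack = list(reversed(self.nodes[taxid].children))
        while stack:
            t = stack.pop()
            yield t
            stack.extend(reversed(self.nodes[t].children))

    def nodes_at_rank(self, rank: str) -> List[int]:
        return [t for t, n in self.nodes.items() if n.rank == rank]

    def subtree(self, taxid: int) -> "TaxonomyTree":
        """A new tree containing ``taxid`` (as root) and all its descendants."""
        sub = TaxonomyTree()
        node = self.nodes[taxid]
        sub.add_node(node.taxid, node.name, node.rank, parent=None)
        for t in self.descendants(taxid):
            n = self.nodes[t]
            sub.add_node(n.taxid, n.name, n.rank, parent=n.parent)
        return sub

    def preorder(self) -> Iterator[int]:
        for r in self.roots:
            yield r
            yield from self.descendants(r)

    def find_by_name(self, name: str, rank: Optional[str] = None) -> List[int]:
        return [
            t
            for t, n in self.nodes.items()
            if n.name == name and (rank is None or n.rank == rank)
        ]

    def depth(self, taxid: int) -> int:
        return sum(1 for _ in self.ancestors(taxid))

    def merge(self, other: "TaxonomyTree") -> None:
        """Union ``other`` into this tree in place.

        Nodes are matched by taxid; conflicting name/rank/parentage is an
        error because two reports from one classifier database must agree.
        """
        for taxid in other.preorder():
            node = other.nodes[taxid]
            if taxid in self.nodes:
                mine = self.nodes[taxid]
                if (mine.name, mine.rank, mine.parent) != (node.name, node.rank, node.parent):
                    raise ValueError(
                        f"conflicting definitions of taxid {taxid}: "
                        f"{(mine.name, mine.rank, mine.parent)} vs "
                        f"{(node.name, node.rank, node.parent)}"
                    )
            else:
                self.add_node(taxid, node.name, node.rank, parent=node.parent)


def read_kraken2_report(path: str | os.PathLike):
    """Parse a Kraken2 report into a taxonomy tree plus direct-read counts.

    Returns ``(tree, counts)`` where ``counts`` maps taxid -> direct reads
    (column 3).  The ``unclassified`` row (taxid 0) is kept as a rank-less
    root so round-tripping preserves the file; downstream bacterial
    filtering removes it.

    Raises :class:`Kraken2ParseError` with the offending line number on
    malformed input, and on an empty file.
    """
    from necmil.cohort import SampleCounts  # local import to avoid a cycle

    tree = TaxonomyTree()
    counts: Dict[int, int] = {}
    # stack of (depth, taxid) along the current root-to-leaf path
    stack: List[tuple] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            n_lines += 1
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise Kraken2ParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated fields, got {len(fields)}"
                )
            _, _, direct_s, code, taxid_s, padded = fields[:6]
            try:
                direct = int(direct_s)
                taxid = int(taxid_s)
            except ValueError as e:
                raise Kraken2ParseError(f"{path}: line {lineno}: {e}") from None
            if direct < 0:
                raise Kraken2ParseError(f"{path}: line {lineno}: negative read count")
            name = padded.lstrip(" ")
            indent = len(padded) - len(name)
            if indent % 2:
                raise Kraken2ParseError(f"{path}: line {lineno}: odd indentation width {indent}")
            depth = indent // 2
            rank = rank_from_code(code)
            while stack and stack[-1][0] >= depth:
                stack.pop()
            parent = stack[-1][1] if stack else None
            if taxid in tree:
                raise Kraken2ParseError(f"{path}: line {lineno}: duplicate taxid {taxid}")
            tree.add_node(taxid, name, rank, parent=parent)
            counts[taxid] = direct
            stack.append((depth, taxid))
    if n_lines == 0:
        raise Kraken2ParseError(f"{path}: empty report")
    sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return tree, SampleCounts(sample_id=sample_id, patient_id="", day_of_life=0, counts=counts)


def _clade_counts(tree: TaxonomyTree, counts: Dict[int, int]) -> Dict[int, int]:
    clade: Dict[int, int] = {}
    # postorder accumulation
    order = list(tree.preorder())
    for taxid in reversed(order):
        total = counts.get(taxid, 0)
        for c in tree.nodes[taxid].children:
            total += clade[c]
        clade[taxid] = total
    return clade


def write_kraken2_report(tree: TaxonomyTree, counts: Dict[int, int], path: str | os.PathLike) -> None:
    """Write ``counts`` over ``tree`` in the Kraken2 report dialect.

    Clade read counts and percentages are recomputed from the direct
    counts; re-parsing the file reproduces the tree and the direct counts
    exactly.
    """
    clade = _clade_counts(tree, counts)
    total = sum(clade[r] for r in tree.roots)
    lines = []
    for taxid in tree.preorder():
        node = tree.nodes[taxid]
        depth = tree.depth(taxid)
        pct = 100.0 * clade[taxid] / total if total else 0.0
        code = "U" if taxid == 0 else _RANK_TO_CODE[node.rank]
        lines.append(
            f"{pct:6.2f}\t{clade[taxid]}\t{counts.get(taxid, 0)}\t{code}\t{taxid}\t"
            f"{'  ' * depth}{node.name}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
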