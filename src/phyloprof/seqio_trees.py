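"""Alignment and tree I/O, canonical bipartitions, supermatrix concatenation.

Alignments are read/written as FASTA (wrapped at 60 columns) or relaxed
PHYLIP (single ``ntax nchar`` header).  Trees are newick; tree samples are
one newick per non-empty line (the ultrafast-bootstrap dialect).  All split
operations treat trees as unrooted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "NewickError",
    "SequenceRecord",
    "Alignment",
    "PartitionedSupermatrix",
    "Tree",
    "TreeSample",
    "Bipartition",
    "read_alignment",
    "write_alignment",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "tree_bipartitions",
    "concatenate_markers",
    "format_partitions",
]

GAP = "-"


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


class NewickError(ValueError):
    """Raised for malformed newick input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise AlignmentError(f"invalid sequence id: {self.id!r}")
        if not self.residues:
            raise AlignmentError(f"empty residues for sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length sequence records."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise AlignmentError("alignment has no sequences")
        length = len(records[0])
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise AlignmentError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if len(rec) != length:
                raise AlignmentError(
                    f"sequence {rec.id!r} has length {len(rec)}, expected {length}"
                )
        self.records: list[SequenceRecord] = records
        self.length: int = length

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"Alignment({len(self.records)} sequences x {self.length} columns)"

    def to_array(self) -> np.ndarray:
        """Return the alignment as a 2-D array of single characters."""
        return np.array([list(r.residues) for r in self.records], dtype="U1")

    @classmethod
    def from_array(cls, ids: Sequence[str], array: np.ndarray) -> "Alignment":
        if array.ndim != 2 or array.shape[0] != len(ids):
            raise AlignmentError("array shape does not match ids")
        return cls(
            [SequenceRecord(i, "".join(row)) for i, row in zip(ids, array)]
        )

    def select_columns(self, indices: Sequence[int]) -> "Alignment":
        """Sub-alignment restricted to ``indices`` (kept in the given order)."""
        arr = self.to_array()[:, list(indices)]
        return Alignment.from_array(self.ids, arr)


@dataclass
class PartitionedSupermatrix:
    """A concatenated alignment with an ordered marker partition table.

    Partitions are (name, start, end) half-open 0-based column intervals
    that tile ``[0, alignment.length)``.
    """

    alignment: Alignment
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.partitions:
            if start != pos or end <= start:
                raise AlignmentError(
                    f"partition {name!r} [{start},{end}) does not tile the matrix"
                )
            pos = end
        if pos != self.alignment.length:
            raise AlignmentError(
                f"partitions cover {pos} columns, alignment has {self.alignment.length}"
            )


@dataclass(frozen=True)
class Bipartition:
    """A canonical unrooted split of a taxon set.

    The canonical side is the side *not* containing the lexicographically
    smallest taxon label, which makes equality and hashing orientation-free.
    """

    side: frozenset
    universe: frozenset

    @classmethod
    def canonical(cls, side: Iterable[str], universe: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        universe = frozenset(universe)
        if not side or not side < universe:
            raise ValueError("side must be a proper non-empty subset of universe")
        if min(universe) in side:
            side = universe - side
        return cls(side, universe)

    @property
    def is_trivial(self) -> bool:
        n = len(self.universe)
        return len(self.side) < 2 or len(self.side) > n - 2

    def complement_side(self) -> frozenset:
        return self.universe - self.side


class Tree:
    """A leaf-labelled tree treated as unrooted for all split operations.

    Wraps a :class:`dendropy.Tree`; branch lengths and internal-node labels
    (support values) are preserved when present.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dupes}")
        self.taxa: frozenset = frozenset(labels)
        self._splits: Optional[frozenset] = None

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    def __repr__(self) -> str:
        return f"Tree({len(self.taxa)} leaves)"

    def newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    def bipartitions(self, include_trivial: bool = False) -> frozenset:
        if include_trivial:
            return frozenset(tree_bipartitions(self, include_trivial=True))
        if self._splits is None:
            self._splits = frozenset(tree_bipartitions(self, include_trivial=False))
        return self._splits


@dataclass
class TreeSample:
    """An ordered, equally-weighted collection of trees on a common taxon set."""

    trees: list[Tree]
    taxa: frozenset

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree sample")
        for i, t in enumerate(self.trees):
            if t.taxa != self.taxa:
                raise ValueError(f"tree {i} has leaf set differing from sample taxa")

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Alignment I/O

_FORMATS = ("fasta", "phylip-relaxed")


def _check_format(format: str) -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}; use one of {_FORMATS}")


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read an alignment from ``path`` in FASTA or relaxed PHYLIP format.

    Sequence order follows the file; gap characters are preserved.  Ragged
    sequences or duplicate ids raise :class:`AlignmentError`.
    """
    _check_format(format)
    path = Path(path)
    if format == "fasta":
        records = [
            SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
        ]
        return Alignment(records)
    try:
        msa = AlignIO.read(str(path), "phylip-relaxed")
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as relaxed PHYLIP: {exc}") from exc
    return Alignment([SequenceRecord(rec.id, str(rec.seq)) for rec in msa])


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write ``aln`` to ``path``; round-trips exactly through read_alignment."""
    _check_format(format)
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in aln.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.residues), 60):
                    fh.write(rec.residues[i : i + 60] + "\n")
        return
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r.residues), id=r.id, description="") for r in aln.records]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, "phylip-relaxed")


# ---------------------------------------------------------------------------
# Trees

def parse_newick(text: str) -> Tree:
    """Parse a single newick string (must end with ';') into a :class:`Tree`."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError("newick string must terminate with ';'")
    if stripped.count("(") != stripped.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    return Tree(dtree)


def write_newick(tree: Tree) -> str:
    return tree.newick()


def read_tree_sample(path) -> TreeSample:
    """Read a one-newick-per-line tree sample; taxa = leaf set of the first tree."""
    trees: list[Tree] = []
    taxa: Optional[frozenset] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tree = parse_newick(line)
            if taxa is None:
                taxa = tree.taxa
            elif tree.taxa != taxa:
                missing = sorted(taxa - tree.taxa)
                extra = sorted(tree.taxa - taxa)
                raise ValueError(
                    f"line {lineno}: leaf set differs from first tree "
                    f"(missing={missing}, extra={extra})"
                )
            trees.append(tree)
    if taxa is None:
        raise ValueError(f"no trees found in {path}")
    return TreeSample(trees=trees, taxa=taxa)


def _leaf_sets(dtree: dendropy.Tree) -> dict:
    """Leaf-label set per node, by postorder accumulation."""
    sets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: frozenset = frozenset()
            for child in node.child_nodes():
                acc = acc | sets[child]
            sets[node] = acc
    return sets


def tree_bipartitions(tree: Tree, include_trivial: bool = False) -> set:
    """Canonical bipartitions of ``tree``, one per internal edge.

    The tree is treated as unrooted: complementary sides induced by a
    degree-2 root collapse to the same canonical split.  Trivial (leaf)
    splits are excluded unless ``include_trivial``.
    """
    dtree = tree._dtree
    universe = tree.taxa
    n = len(universe)
    sets = _leaf_sets(dtree)
    root = dtree.seed_node
    out: set = set()
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        side = sets[node]
        if node.is_leaf():
            if include_trivial and n >= 2:
                out.add(Bipartition.canonical(side, universe))
            continue
        if len(side) >= n - 1:
            # edge below a degree-2 root: complement is a leaf or empty
            if include_trivial and 0 < n - len(side):
                out.add(Bipartition.canonical(side, universe))
            continue
        bip = Bipartition.canonical(side, universe)
        if bip.is_trivial and not include_trivial:
            continue
        out.add(bip)
    if not include_trivial:
        out = {b for b in out if not b.is_trivial}
    return out


# ---------------------------------------------------------------------------
# Concatenation

def concatenate_markers(
    markers: Sequence[tuple[str, Alignment]],
    taxa: Optional[Sequence[str]] = None,
) -> PartitionedSupermatrix:
    """Concatenate per-marker alignments into a gap-filled supermatrix.

    Row order is the supplied ``taxa`` list, or taxa by first appearance
    across markers.  Taxa absent from a marker get ``-`` across its columns.
    """
    markers = list(markers)
    if not markers:
        raise AlignmentError("no markers to concatenate")
    if taxa is None:
        order: list[str] = []
        seen: set[str] = set()
        for _, aln in markers:
            for tid in aln.ids:
                if tid not in seen:
                    seen.add(tid)
                    order.append(tid)
    else:
        order = list(taxa)
        allowed = set(order)
        for name, aln in markers:
            unknown = [tid for tid in aln.ids if tid not in allowed]
            if unknown:
                raise AlignmentError(
                    f"marker {name!r} contains taxa missing from the taxa list: {unknown}"
                )
    parts: list[tuple[str, int, int]] = []
    rows: dict[str, list[str]] = {tid: [] for tid in order}
    pos = 0
    for name, aln in markers:
        by_id = {r.id: r.residues for r in aln.records}
        for tid in order:
            rows[tid].append(by_id.get(tid, GAP * aln.length))
        parts.append((name, pos, pos + aln.length))
        pos += aln.length
    records = [SequenceRecord(tid, "".join(rows[tid])) for tid in order]
    return PartitionedSupermatrix(alignment=Alignment(records), partitions=parts)


def format_partitions(partitions: Sequence[tuple[str, int, int]]) -> str:
    """RAxML-style partition table, 1-based inclusive intervals."""
    return "\n".join(f"{name} = {start + 1}-{end}" for name, start, end in partitions)
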