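"""Trees, alignments and the distances between them.

Rooted leaf-labelled trees are the universal currency of the package:
species trees carry branch lengths in coalescent units, gene trees in
substitutions per site (or coalescent units when they come straight out of
the simulator).  Trees are represented as :class:`dendropy.Tree` objects;
this module adds the operations the discordance analyses need — strict
newick round-tripping, unrooted bipartition sets, Robinson–Foulds
distances, and a canonical topology key for tallying tree shapes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TreeError",
    "ParseError",
    "Bipartition",
    "Alignment",
    "parse_newick",
    "write_newick",
    "read_tree_file",
    "write_tree_file",
    "leaf_labels",
    "bipartitions",
    "rf_distance",
    "topology_key",
    "restrict_tree",
    "concatenate",
    "strip_gapped_columns",
]

MISSING_CHARS = frozenset("-N")  # gap + ambiguous, case-insensitive


class TreeError(ValueError):
    """Invalid tree input (leaf-set mismatch, too few leaves, ...)."""


class ParseError(TreeError):
    """Malformed newick or duplicated leaf labels."""


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick string into a rooted tree.

    Branch lengths are optional; absent lengths stay ``None`` rather than
    being coerced to zero.  Duplicate leaf labels and unbalanced
    parentheses raise :class:`ParseError` naming the offending token.
    """
    if not text.strip():
        raise ParseError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"newick parse failed: {exc}") from exc
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if not lab:
            raise ParseError("unlabeled or empty leaf")
        if lab in seen:
            raise ParseError(f"duplicate leaf label: {lab!r}")
        seen.add(lab)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick with branch lengths at 10 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    return s.strip()


def read_tree_file(path: str | Path) -> list[dendropy.Tree]:
    """Read a one-newick-per-line tree file."""
    trees = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            trees.append(parse_newick(line))
    return trees


def write_tree_file(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    Path(path).write_text("".join(write_newick(t) + "\n" for t in trees))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# bipartitions and RF distance


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split: the two leaf-label sets induced by one internal edge.

    Equality and hashing ignore which side is which, so a bipartition
    equals its own complement.
    """

    side_a: frozenset[str] = field(compare=False)
    side_b: frozenset[str] = field(compare=False)
    _key: frozenset[frozenset[str]] = field(init=False, repr=False, compare=True)

    def __post_init__(self) -> None:
        if self.side_a & self.side_b:
            raise TreeError("bipartition sides overlap")
        object.__setattr__(self, "_key", frozenset((self.side_a, self.side_b)))

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def conflicts_with(self, other: "Bipartition") -> bool:
        """Two splits on the same leaf set conflict iff all four
        pairwise side intersections are non-empty (standard compatibility)."""
        for x in (self.side_a, self.side_b):
            for y in (other.side_a, other.side_b):
                if not (x & y):
                    return False
        return True

    def restrict(self, taxa: frozenset[str]) -> "Bipartition":
        return Bipartition(self.side_a & taxa, self.side_b & taxa)


def bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[Bipartition]:
    """The unrooted bipartition set of a tree.

    Each internal edge contributes the split (clade below, rest).  The two
    root-adjacent edges of a rooted binary tree induce the same unrooted
    split; the set collapses them.  Multifurcating nodes simply contribute
    fewer splits.
    """
    all_leaves = frozenset(leaf_labels(tree))
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bp = Bipartition(below, all_leaves - below)
        if include_trivial or not bp.is_trivial():
            out.add(bp)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: the symmetric difference of the two trees'
    non-trivial unrooted bipartition sets.

    Computed on unrooted splits, so root placement never changes it.
    Requires identical leaf sets of at least 4 taxa.
    """
    s1, s2 = frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))
    if s1 != s2:
        raise TreeError(
            f"leaf sets differ: only-in-first={sorted(s1 - s2)}, only-in-second={sorted(s2 - s1)}"
        )
    if len(s1) < 4:
        raise TreeError(f"need >=4 shared leaves, got {len(s1)}")
    return len(bipartitions(t1) ^ bipartitions(t2))


def topology_key(tree: dendropy.Tree) -> str:
    """Canonical topology string: invariant under child order and branch
    lengths.  Children are sorted lexicographically at every node, so two
    trees get equal keys iff they have the same rooted topology."""

    def rec(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(rec(c) for c in node.child_nodes())) + ")"

    if len(tree.leaf_nodes()) < 3:
        raise TreeError("topology key needs >=3 leaves")
    return rec(tree.seed_node) + ";"


def restrict_tree(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Prune the tree down to the given leaf labels (path lengths along
    retained edges are preserved; unifurcations are suppressed)."""
    keep = set(taxa)
    have = set(leaf_labels(tree))
    missing = keep - have
    if missing:
        raise TreeError(f"taxa absent from tree: {sorted(missing)}")
    return tree.extract_tree_with_taxa_labels(labels=keep)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """An in-memory multiple sequence alignment over {A,C,G,T,-,N}.

    ``data`` is a (taxa x sites) byte matrix; rows follow ``taxa`` order.
    Comparisons are case-insensitive (everything is upper-cased on entry).
    """

    taxa: list[str]
    data: np.ndarray  # dtype 'S1', shape (n_taxa, n_sites)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels in alignment")
        self.data = np.char.upper(np.asarray(self.data, dtype="S1"))
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment matrix shape does not match taxa")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, str]]) -> "Alignment":
        taxa = [name for name, _ in rows]
        seqs = [seq for _, seq in rows]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(taxa), -1)
        return cls(taxa, mat.copy())

    def row(self, taxon: str) -> np.ndarray:
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon not in alignment: {taxon!r}") from None
        return self.data[i]

    def sequence(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode()

    # -- I/O (Biopython behind the scenes) ---------------------------------

    @classmethod
    def read(cls, path: str | Path, fmt: str = "fasta") -> "Alignment":
        fmt = {"phylip": "phylip-relaxed"}.get(fmt, fmt)
        records = list(SeqIO.parse(str(path), fmt))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_rows([(r.id, str(r.seq)) for r in records])

    def write(self, path: str | Path, fmt: str = "fasta") -> None:
        fmt = {"phylip": "phylip-relaxed"}.get(fmt, fmt)
        records = [
            SeqRecord(Seq(self.sequence(t)), id=t, description="") for t in self.taxa
        ]
        with open(path, "w") as fh:
            if fmt == "fasta":
                SeqIO.write(records, fh, "fasta")
            else:
                AlignIO.write(MultipleSeqAlignment(records), fh, fmt)

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for t in self.taxa:
            buf.write(f">{t}\n{self.sequence(t)}\n")
        return buf.getvalue()


def concatenate(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate loci sharing the same taxon set into a super-alignment."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = alignments[0].taxa
    blocks = [alignments[0].data]
    for a in alignments[1:]:
        if set(a.taxa) != set(taxa):
            raise ValueError("alignments disagree on taxon sets")
        blocks.append(a.data if a.taxa == taxa else np.stack([a.row(t) for t in taxa]))
    return Alignment(list(taxa), np.concatenate(blocks, axis=1))


def strip_gapped_columns(aln: Alignment, threshold: float) -> Alignment:
    """Drop alignment columns whose missing-data fraction exceeds ``threshold``.

    A column is retained iff its proportion of '-' or 'N' characters is
    <= threshold (a column at exactly the threshold survives).  Row order
    is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if aln.n_sites == 0 or aln.n_taxa == 0:
        raise ValueError("empty alignment")
    missing = (aln.data == b"-") | (aln.data == b"N")
    frac = missing.mean(axis=0)
    return Alignment(list(aln.taxa), aln.data[:, frac <= threshold])
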