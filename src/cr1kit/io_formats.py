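"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open on the plus strand with an
explicit strand flag; 1-based inclusive conventions (the 12-column tabular
hit dialect) are converted at the I/O boundary and nowhere else.
Minus-strand hits are stored normalised (start < end).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import dendropy

from .dna import VALID_NUCLEOTIDES

__all__ = [
    "Interval",
    "GenomeAssembly",
    "AlignmentHit",
    "SpeciesTree",
    "compute_n50",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_species_tree",
    "write_insertion_table",
    "read_insertion_table",
]


# ---------------------------------------------------------------------------
# core coordinate / container types


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval on a named scaffold."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def compute_n50(lengths: list[int]) -> int:
    """Scaffold N50: length L such that scaffolds >= L hold half the assembly."""
    if not lengths:
        raise ValueError("cannot compute N50 of an empty assembly")
    total = sum(lengths)
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if 2 * acc >= total:
            return n
    return min(lengths)  # pragma: no cover


class GenomeAssembly:
    """A genome assembly: ordered scaffold_id -> uppercase nucleotide sequence."""

    def __init__(self, species_id: str, scaffolds: dict[str, str]):
        if not scaffolds:
            raise ValueError(f"assembly {species_id!r} has no scaffolds")
        clean: dict[str, str] = {}
        for sid, seq in scaffolds.items():
            if not seq:
                raise ValueError(f"scaffold {sid!r} is empty")
            seq = seq.upper()
            bad = set(seq) - VALID_NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"scaffold {sid!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            if sid in clean:
                raise ValueError(f"duplicate scaffold id {sid!r}")
            clean[sid] = seq
        self.species_id = species_id
        self.scaffolds = clean

    @property
    def scaffold_n50(self) -> int:
        return compute_n50([len(s) for s in self.scaffolds.values()])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def fetch(self, interval: Interval) -> str:
        """Plus-strand sequence of an interval (bounds checked)."""
        seq = self.scaffolds[interval.scaffold_id]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds scaffold length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenomeAssembly({self.species_id!r}, {len(self.scaffolds)} scaffolds, "
            f"{self.total_length} bp, N50={self.scaffold_n50})"
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment hit of a query sequence against a subject genome."""

    query_id: str
    subject_interval: Interval
    query_start: int
    query_end: int
    percent_identity: float
    aligned_length: int
    mismatches: int
    gap_openings: int
    score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if self.aligned_length < self.mismatches:
            raise ValueError("aligned_length < mismatches")

    @property
    def strand(self) -> str:
        return self.subject_interval.strand


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """Rooted species tree over assembly species ids.

    Branches are identified by the clade below them: the branch id is the
    '+'-joined sorted leaf labels of the child clade (e.g. ``"A"`` for a
    terminal branch, ``"A+B"`` for the branch above the (A,B) ancestor).
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("leaf labels are not unique")
        self._tree = tree
        self.leaves: list[str] = sorted(leaves)
        # per-node clade signatures
        self._clade: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._clade[id(node)] = frozenset([node.taxon.label])
            else:
                s: set[str] = set()
                for ch in node.child_nodes():
                    s |= self._clade[id(ch)]
                self._clade[id(node)] = frozenset(s)
        self._nodes_by_branch: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # the root subtends no branch
            self._nodes_by_branch[self.branch_id(self._clade[id(node)])] = node

    @staticmethod
    def branch_id(clade: frozenset[str] | set[str]) -> str:
        return "+".join(sorted(clade))

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:
            raise ValueError(f"invalid newick tree: {exc}") from exc
        return cls(tree)

    @property
    def branch_ids(self) -> list[str]:
        return sorted(self._nodes_by_branch)

    def clade_of(self, branch: str) -> frozenset[str]:
        return self._clade[id(self._nodes_by_branch[branch])]

    def branch_length(self, branch: str) -> float | None:
        el = self._nodes_by_branch[branch].edge.length
        return None if el is None else float(el)

    def has_branch_lengths(self) -> bool:
        return all(self.branch_length(b) is not None for b in self.branch_ids)

    def root_path_branches(self, leaf: str) -> list[str]:
        """Branch ids from the root's child edge down to the terminal branch."""
        if leaf not in self.leaves:
            raise KeyError(f"unknown leaf {leaf!r}")
        node = self._nodes_by_branch[leaf]
        path = []
        while node.parent_node is not None:
            path.append(self.branch_id(self._clade[id(node)]))
            node = node.parent_node
        return list(reversed(path))

    def preorder_branches(self) -> list[tuple[str, float | None]]:
        """(branch_id, length) in deterministic preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            bid = self.branch_id(self._clade[id(node)])
            el = node.edge.length
            out.append((bid, None if el is None else float(el)))
        return out

    def parent_branch(self, branch: str) -> str | None:
        node = self._nodes_by_branch[branch].parent_node
        if node is None or node.parent_node is None:
            return None
        return self.branch_id(self._clade[id(node)])

    def mrca_branch(self, taxa: set[str]) -> str:
        """Branch above the MRCA of ``taxa`` (a terminal branch for one leaf)."""
        unknown = set(taxa) - set(self.leaves)
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        if not taxa:
            raise ValueError("empty taxon set")
        for node in self._tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            if set(taxa) <= self._clade[id(node)]:
                return self.branch_id(self._clade[id(node)])
        # taxa spread over both sides of the root: no subtending branch
        raise ValueError("MRCA is the root; no branch subtends it")

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def read_species_tree(path: str | os.PathLike) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return SpeciesTree(tree)


# ---------------------------------------------------------------------------
# FASTA


def _open_maybe_gzip(path: str | os.PathLike, mode: str = "rt"):
    path = str(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | os.PathLike, species_id: str | None = None) -> GenomeAssembly:
    """Load a (possibly gzipped) FASTA file as a :class:`GenomeAssembly`.

    The header token before the first whitespace becomes the scaffold id.
    """
    from Bio import SeqIO

    if species_id is None:
        base = os.path.basename(str(path))
        for ext in (".gz", ".fasta", ".fa", ".fna"):
            if base.endswith(ext):
                base = base[: -len(ext)]
        species_id = base
    scaffolds: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in scaffolds:
                raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
            scaffolds[rec.id] = str(rec.seq)
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(species_id, scaffolds)


def write_fasta(assembly_or_entries, path: str | os.PathLike, width: int = 70) -> None:
    """Write a GenomeAssembly or a {label: seq} mapping as FASTA."""
    entries = (
        assembly_or_entries.scaffolds
        if isinstance(assembly_or_entries, GenomeAssembly)
        else assembly_or_entries
    )
    with open(path, "w") as fh:
        for label, seq in entries.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt-6 dialect)

_HIT_COLUMNS = 12


def read_tabular_hits(path: str | os.PathLike) -> list[AlignmentHit]:
    """Parse the 12-column tab-separated hit dialect.

    Columns: query, subject, %identity, length, mismatches, gapopen,
    qstart, qend, sstart, send, evalue, bitscore — 1-based inclusive
    coordinates, with sstart > send encoding a minus-strand hit.
    """
    hits: list[AlignmentHit] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(fields)}"
                )
            try:
                (query, subject, pident, length, mism, gapo,
                 qstart, qend, sstart, send, evalue, bitscore) = fields
                pident = float(pident)
                length = int(length)
                mism = int(mism)
                gapo = int(gapo)
                qstart, qend = int(qstart), int(qend)
                sstart, send = int(sstart), int(send)
                evalue = float(evalue)
                bitscore = float(bitscore)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if sstart <= send:
                interval = Interval(subject, sstart - 1, send, "+")
            else:
                interval = Interval(subject, send - 1, sstart, "-")
            hits.append(
                AlignmentHit(
                    query_id=query,
                    subject_interval=interval,
                    query_start=qstart - 1,
                    query_end=qend,
                    percent_identity=pident,
                    aligned_length=length,
                    mismatches=mism,
                    gap_openings=gapo,
                    score=bitscore,
                    e_value=evalue,
                )
            )
    return hits


def write_tabular_hits(hits: list[AlignmentHit], path: str | os.PathLike) -> None:
    """Inverse of :func:`read_tabular_hits` (1-based inclusive on output)."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.subject_interval
            if iv.strand == "+":
                sstart, send = iv.start + 1, iv.end
            else:
                sstart, send = iv.end, iv.start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, iv.scaffold_id,
                        f"{h.percent_identity:.2f}", h.aligned_length,
                        h.mismatches, h.gap_openings,
                        h.query_start + 1, h.query_end,
                        sstart, send,
                        0.0 if h.e_value is None else h.e_value,
                        f"{h.score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# insertion tables (LocusCall / BranchAssignment TSVs)


def write_insertion_table(records, path: str | os.PathLike) -> None:
    """Persist LocusCall or BranchAssignment records as a TSV (round-trip safe)."""
    from .presence_absence import LocusCall
    from .parsimony import BranchAssignment

    records = list(records)
    kind = "locus_call"
    if records and isinstance(records[0], BranchAssignment):
        kind = "branch_assignment"
    with open(path, "w") as fh:
        if kind == "locus_call":
            fh.write("#table=locus_call\n")
            fh.write("insertion_id\ttarget_species\tcall\treason\ttarget_gap\n")
            for r in records:
                if not isinstance(r, LocusCall):
                    raise TypeError("mixed record types in insertion table")
                gap = "" if r.target_gap is None else str(r.target_gap)
                fh.write(f"{r.insertion_id}\t{r.target_species}\t{r.call}\t{r.reason}\t{gap}\n")
        else:
            fh.write("#table=branch_assignment\n")
            fh.write("insertion_id\tfamily_id\tbranch\tsupport\tambiguous_range\n")
            for r in records:
                if not isinstance(r, BranchAssignment):
                    raise TypeError("mixed record types in insertion table")
                rng = ",".join(r.ambiguous_range)
                fh.write(f"{r.insertion_id}\t{r.family_id}\t{r.branch}\t{r.support}\t{rng}\n")


def read_insertion_table(path: str | os.PathLike):
    """Read a table written by :func:`write_insertion_table`."""
    from .presence_absence import LocusCall, CALLS, REASONS
    from .parsimony import BranchAssignment, SUPPORT_LEVELS

    with open(path) as fh:
        header = fh.readline().strip()
        if header == "#table=locus_call":
            kind = "locus_call"
        elif header == "#table=branch_assignment":
            kind = "branch_assignment"
        else:
            raise ValueError(f"{path}: unrecognised insertion-table header {header!r}")
        fh.readline()  # column header
        out = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if kind == "locus_call":
                ins, target, call, reason, gap = fields
                if call not in CALLS:
                    raise ValueError(f"{path}:{lineno}: unknown call {call!r}")
                if reason not in REASONS:
                    raise ValueError(f"{path}:{lineno}: unknown reason {reason!r}")
                out.append(
                    LocusCall(
                        insertion_id=ins,
                        target_species=target,
                        call=call,
                        reason=reason,
                        target_gap=None if gap == "" else int(gap),
                    )
                )
            else:
                ins, fam, branch, support, rng = fields
                if support not in SUPPORT_LEVELS:
                    raise ValueError(f"{path}:{lineno}: unknown support {support!r}")
                out.append(
                    BranchAssignment(
                        insertion_id=ins,
                        family_id=fam,
                        branch=branch,
                        support=support,
                        ambiguous_range=tuple(x for x in rng.split(",") if x),
                    )
                )
    return out
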