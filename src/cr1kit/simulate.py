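"""Simulate genome evolution along a species tree with CR1 insertion events.

The generator produces ground-truthed inputs for every pipeline stage:
an ancestral genome evolves down a rooted tree with branch lengths in Myr,
accumulating per-branch Jukes–Cantor substitutions, small indels, and CR1
insertions (full-length or 5'-truncated, flanked by target-site
duplications).  Each leaf yields a :class:`GenomeAssembly`; every insertion
yields a :class:`SimTruth` with its origin branch and per-leaf locus.

Scaffolds are represented internally as block lists so that insertion loci
can be tracked exactly through subsequent edits: background blocks carry
no label, element blocks carry their insertion id (and are split, not
relabelled, when a later insertion nests inside them).  No excision is
simulated — absence always means the pre-insertion state, matching the
assumption of the presence/absence scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dna import random_dna, revcomp
from .io_formats import GenomeAssembly, Interval, SpeciesTree, compute_n50

__all__ = [
    "FamilySpec",
    "SimConfig",
    "SimTruth",
    "make_cr1_consensus",
    "default_families",
    "simulate",
    "fragment_assembly",
    "remap_interval",
]


@dataclass(frozen=True)
class FamilySpec:
    """A simulated CR1 family: consensus sequence plus where it is active."""

    family_id: str
    consensus: str
    active_branches: tuple[str, ...] | None = None  # None = active on all branches
    microsat_motif: str | None = None  # concrete terminal motif (enables tail slippage)

    def __post_init__(self) -> None:
        if len(self.consensus) < 2700:
            raise ValueError(
                f"family {self.family_id!r}: consensus must be >= 2700 bp so "
                f"full-length copies pass the discovery filter"
            )


@dataclass
class SimConfig:
    """Study conditions for one simulation run (the seed fully determines output)."""

    tree: SpeciesTree | str
    families: list[FamilySpec]
    rng_seed: int
    ancestral_genome_length: int = 1_000_000
    n_scaffolds: int = 4
    insertion_rate: float = 5.0  # insertions per Myr, whole genome
    total_insertions: int | None = None  # exact count split over branches by length
    prob_full_length: float = 0.2
    truncation_min_bp: int = 50  # minimum 5' truncation of a truncated copy
    preserve_3prime_bp: int = 300  # tail (hairpin + microsatellite) always retained
    retained_length_range: tuple[int, int] | None = None  # overrides the default model
    tsd_length_range: tuple[int, int] = (2, 20)
    substitution_rate: float = 0.002  # substitutions/site/Myr (Jukes–Cantor)
    indel_rate: float = 0.0  # indels/site/Myr
    indel_max_bp: int = 5
    min_insertion_spacing_bp: int = 0  # keep loci this far apart (0 = off)
    allow_nested: bool = True
    # microsatellite slippage: extra tail-motif copies deposited beyond the
    # annotated element end (they become flank sequence, as when annotation
    # cuts a variable-length terminal array at the consensus boundary)
    extra_microsat_copies: tuple[int, int] = (0, 8)

    def __post_init__(self) -> None:
        if isinstance(self.tree, str):
            self.tree = SpeciesTree.from_newick(self.tree)
        for r in (self.insertion_rate, self.substitution_rate, self.indel_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not self.families:
            raise ValueError("at least one family is required")
        if not self.tree.has_branch_lengths():
            raise ValueError("species tree must carry branch lengths (Myr)")


@dataclass
class SimTruth:
    """Ground truth for one simulated insertion."""

    insertion_id: str
    family_id: str
    origin_branch: str
    anatomy: str  # "full_length" | "truncated"
    strand: str
    tsd: str
    element_length: int  # length at insertion time
    loci: dict[str, Interval | None] = field(default_factory=dict)  # per leaf


# ---------------------------------------------------------------------------
# consensus construction

_CODON = {  # one unambiguous codon per amino acid (stop codons excluded)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_FILLER_AA = "ADEFGHIKLNPQRSTVWY"  # avoids M so markers stay unique-ish


def _encode_peptide(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


def make_cr1_consensus(
    rng: np.random.Generator,
    orf_codons: int = 850,
    utr3_bp: int = 260,
    hairpin_stem: int = 10,
    hairpin_loop: int = 8,
    microsat_motif: str = "ATTCTGTG",
    microsat_copies: int = 4,
) -> str:
    """Build a synthetic CR1-style consensus.

    Layout: ATG-initiated single ORF carrying the EN marker at its very 5'
    end and the RT marker mid-ORF, then a 3' UTR ending in a hairpin
    (perfect inverted repeat) directly upstream of a terminal microsatellite
    array.  The ORF starts at position 0 so that any 5' truncation of
    >= 50 bp destroys enough of the EN marker to fail domain detection —
    truncated copies must never classify as full-length.
    """
    from .anatomy import EN_MARKER_AA, RT_MARKER_AA

    en_nt = _encode_peptide(EN_MARKER_AA)  # starts with ATG (marker begins with M)
    rt_nt = _encode_peptide(RT_MARKER_AA)
    n_en = len(EN_MARKER_AA)
    n_rt = len(RT_MARKER_AA)
    mid = (orf_codons - n_en - n_rt) // 2
    tail = orf_codons - n_en - n_rt - mid
    filler = np.array(list(_FILLER_AA))
    mid_aa = "".join(filler[rng.integers(0, len(filler), size=mid)])
    tail_aa = "".join(filler[rng.integers(0, len(filler), size=tail)])
    orf = en_nt + _encode_peptide(mid_aa) + rt_nt + _encode_peptide(tail_aa) + "TAA"
    stem = random_dna(rng, hairpin_stem)
    loop = random_dna(rng, hairpin_loop)
    hairpin = stem + loop + revcomp(stem)
    microsat = microsat_motif * microsat_copies
    spacer_len = utr3_bp - len(hairpin) - len(microsat)
    if spacer_len < 0:
        raise ValueError("utr3_bp too small for hairpin + microsatellite")
    spacer = random_dna(rng, spacer_len)
    return orf + spacer + hairpin + microsat


def default_families(
    rng: np.random.Generator,
    n_families: int = 2,
) -> list[FamilySpec]:
    """A small registry of simulated CR1 families.

    Each family is an independently constructed, structurally valid
    element (own ORF filler, hairpin and 3' spacer; shared EN/RT marker
    cores, as real CR1 families share their domains).  Families alternate
    between the standard octamer microsatellite and the extended 10-mer
    seen in the CR1-W family.
    """
    motifs = ("ATTCTGTG", "AAATTCCGTG")
    letters = "ABCDEFGH"
    families = []
    for i in range(n_families):
        cons = make_cr1_consensus(rng, microsat_motif=motifs[i % 2])
        families.append(
            FamilySpec(f"CR1-sim{letters[i]}", cons, microsat_motif=motifs[i % 2])
        )
    return families


def _mutate_consensus(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected_spans: tuple[tuple[int, int], ...] = (),
) -> str:
    """Substitute a fraction of positions, sparing the 3' tail structure.

    ``protected_spans`` lets callers exempt further regions (e.g. domain
    cores under purifying selection) from substitution.
    """
    tail = 60  # keep hairpin+microsatellite recognisable
    arr = np.array(list(seq))
    allowed = np.ones(len(seq), dtype=bool)
    allowed[len(seq) - tail :] = False
    for lo, hi in protected_spans:
        allowed[lo:hi] = False
    sites = np.nonzero(allowed)[0]
    k = int(round(rate * len(sites)))
    pos = sites[rng.choice(len(sites), size=k, replace=False)]
    for p in pos:
        cur = arr[p]
        alt = [b for b in "ACGT" if b != cur]
        arr[p] = alt[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# block machinery


@dataclass
class _Block:
    label: str | None  # insertion id, or None for background
    seq: str
    anc: int | None = None  # approximate ancestral coordinate of the first base


def _total_length(blocks: list[_Block]) -> int:
    return sum(len(b.seq) for b in blocks)


def _substitute(rng: np.random.Generator, blocks: list[_Block], p_change: float) -> None:
    """Apply Jukes–Cantor substitutions in place.

    ``p_change`` is the probability a site differs after the branch:
    p = 3/4 (1 - e^(-4 d / 3)) for expected d substitutions/site.  Each
    changed site moves to one of the three other bases uniformly.
    """
    if p_change <= 0:
        return
    for block in blocks:
        arr = np.frombuffer(block.seq.encode(), dtype=np.uint8).copy()
        mask = rng.random(len(arr)) < p_change
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # pick one of the 3 alternatives per site
        cur = arr[idx]
        shift = rng.integers(1, 4, size=len(idx))
        code = np.zeros(len(idx), dtype=np.int64)
        for i, b in enumerate(bases):
            code[cur == b] = i
        newcode = (code + shift) % 4
        # sites that are N or other codes stay untouched
        valid = np.isin(cur, bases)
        arr[idx[valid]] = bases[newcode[valid]]
        block.seq = arr.tobytes().decode()


def _apply_indels(
    rng: np.random.Generator, blocks: list[_Block], rate: float, t: float, max_len: int
) -> None:
    if rate <= 0 or t <= 0:
        return
    for block in blocks:
        n = len(block.seq)
        k = rng.poisson(rate * t * n)
        for _ in range(k):
            if len(block.seq) < 2 * max_len + 2:
                break
            pos = int(rng.integers(1, len(block.seq) - max_len - 1))
            size = int(rng.integers(1, max_len + 1))
            if rng.random() < 0.5:  # deletion
                block.seq = block.seq[:pos] + block.seq[pos + size :]
            else:  # insertion
                block.seq = block.seq[:pos] + random_dna(rng, size) + block.seq[pos:]


def _insertion_positions(blocks_by_scaffold: dict[str, list[_Block]]) -> dict[str, list[tuple[int, int]]]:
    """Current element spans per scaffold (for spacing checks)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for sid, blocks in blocks_by_scaffold.items():
        pos = 0
        out = []
        for b in blocks:
            if b.label is not None:
                out.append((pos, pos + len(b.seq)))
            pos += len(b.seq)
        spans[sid] = out
    return spans


def _insert_element(
    rng: np.random.Generator,
    blocks_by_scaffold: dict[str, list[_Block]],
    insertion_id: str,
    element: str,
    tail_slip: str,
    slip_before: bool,
    tsd_len: int,
    config: SimConfig,
    used_sites: dict[str, list[int]],
) -> str | None:
    """Insert an element with a target-site duplication; returns the TSD.

    With a positive ``min_insertion_spacing_bp`` the insertion site (in
    approximate ancestral coordinates) must keep that distance from every
    previously used site in *any* lineage.  This compensates for the
    desk-scale genome: independent insertions at near-identical orthologous
    sites (homoplasy) are vanishingly rare per locus in gigabase genomes
    but common when the same insertion load is packed into a few hundred
    kilobases.  A spacing of 0 disables the registry.
    """
    sids = sorted(blocks_by_scaffold)
    lengths = np.array([_total_length(blocks_by_scaffold[s]) for s in sids], dtype=float)
    spacing = config.min_insertion_spacing_bp
    for _attempt in range(2000):
        sid = sids[int(rng.choice(len(sids), p=lengths / lengths.sum()))]
        blocks = blocks_by_scaffold[sid]
        total = _total_length(blocks)
        if total < 2 * tsd_len + 100:
            continue
        pos = int(rng.integers(50, total - tsd_len - 50))
        # locate block and offset
        acc = 0
        bi, off = None, None
        for i, b in enumerate(blocks):
            if acc <= pos < acc + len(b.seq):
                bi, off = i, pos - acc
                break
            acc += len(b.seq)
        assert bi is not None
        block = blocks[bi]
        if off + tsd_len > len(block.seq):
            continue  # TSD would cross a block boundary; resample
        if block.label is not None and not config.allow_nested:
            continue
        anc_pos = None if block.anc is None else block.anc + off
        if spacing > 0:
            if anc_pos is None:
                continue  # no ancestral coordinate (nested site): cannot verify spacing
            if any(abs(anc_pos - p) < spacing for p in used_sites.get(sid, ())):
                continue
        tsd = block.seq[off : off + tsd_len]
        left = _Block(block.label, block.seq[: off + tsd_len], block.anc)
        # slipped tail copies and the duplicated target site are flank material;
        # on the minus strand the element 3' tail points left, so the slipped
        # copies go before the element block
        slip = _Block(None, tail_slip, anc_pos)
        dup = _Block(None, tsd, anc_pos)
        right_anc = None if block.anc is None else block.anc + off + tsd_len
        right = _Block(block.label, block.seq[off + tsd_len :], right_anc)
        if slip_before:
            new = [left, slip, _Block(insertion_id, element), dup, right]
        else:
            new = [left, _Block(insertion_id, element), slip, dup, right]
        blocks[bi : bi + 1] = [b for b in new if b.seq]
        if anc_pos is not None:
            used_sites.setdefault(sid, []).append(anc_pos)
        return tsd
    return None


# ---------------------------------------------------------------------------
# main simulation


def simulate(config: SimConfig) -> tuple[dict[str, GenomeAssembly], list[SimTruth]]:
    """Run the simulation; deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    tree: SpeciesTree = config.tree  # type: ignore[assignment]

    branches = tree.preorder_branches()
    lengths = np.array([t for _, t in branches], dtype=float)
    total_t = float(lengths.sum())
    if config.total_insertions is not None:
        alloc = rng.multinomial(config.total_insertions, lengths / total_t)
        n_per_branch = {b: int(k) for (b, _), k in zip(branches, alloc)}
    else:
        n_per_branch = {
            b: int(rng.poisson(config.insertion_rate * t)) for b, t in branches
        }
    expected_bp = sum(n_per_branch.values()) * max(len(f.consensus) for f in config.families)
    if expected_bp > 0.8 * config.ancestral_genome_length * 5:
        raise ValueError("insertion load would exceed the genome size")

    # ancestral genome
    per_scaffold = config.ancestral_genome_length // config.n_scaffolds
    ancestor: dict[str, list[_Block]] = {
        f"scf{i + 1}": [_Block(None, random_dna(rng, per_scaffold), anc=0)]
        for i in range(config.n_scaffolds)
    }
    used_sites: dict[str, list[int]] = {}

    truths: dict[str, SimTruth] = {}
    counter = [0]
    assemblies: dict[str, GenomeAssembly] = {}

    def element_for(family: FamilySpec) -> tuple[str, str, str, str]:
        consensus = family.consensus
        if rng.random() < config.prob_full_length:
            seq, kind = consensus, "full_length"
        else:
            if config.retained_length_range is not None:
                lo, hi = config.retained_length_range
                retained = int(rng.integers(lo, hi + 1))
            else:
                amount = int(
                    rng.integers(config.truncation_min_bp, len(consensus) - config.preserve_3prime_bp + 1)
                )
                retained = len(consensus) - amount
            seq, kind = consensus[-retained:], "truncated"
        slip = ""
        if family.microsat_motif is not None:
            lo, hi = config.extra_microsat_copies
            n_extra = int(rng.integers(lo, hi + 1))
            motif_instance = consensus[-len(family.microsat_motif):]
            slip = motif_instance * n_extra
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            return revcomp(seq), kind, strand, revcomp(slip)
        return seq, kind, strand, slip

    def evolve(node_blocks: dict[str, list[_Block]], branch: str | None, clade: frozenset[str]) -> None:
        # branch is None only at the root (no edge above it)
        if branch is not None:
            t = tree.branch_length(branch) or 0.0
            d = config.substitution_rate * t
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            for sid in sorted(node_blocks):
                _substitute(rng, node_blocks[sid], p_change)
                _apply_indels(rng, node_blocks[sid], config.indel_rate, t, config.indel_max_bp)
            active = [
                f
                for f in config.families
                if f.active_branches is None or branch in f.active_branches
            ]
            for _ in range(n_per_branch.get(branch, 0)):
                if not active:
                    break
                family = active[int(rng.integers(0, len(active)))]
                element, kind, strand, tail_slip = element_for(family)
                tsd_len = int(rng.integers(config.tsd_length_range[0], config.tsd_length_range[1] + 1))
                counter[0] += 1
                ins_id = f"ins{counter[0]:05d}"
                tsd = _insert_element(
                    rng, node_blocks, ins_id, element, tail_slip, strand == "-",
                    tsd_len, config, used_sites,
                )
                if tsd is None:
                    counter[0] -= 1
                    continue
                truths[ins_id] = SimTruth(
                    insertion_id=ins_id,
                    family_id=family.family_id,
                    origin_branch=branch,
                    anatomy=kind,
                    strand=strand,
                    tsd=tsd,
                    element_length=len(element),
                )
        if len(clade) == 1:
            leaf = next(iter(clade))
            scaffolds = {}
            for sid in sorted(node_blocks):
                blocks = node_blocks[sid]
                scaffolds[sid] = "".join(b.seq for b in blocks)
                pos = 0
                spans: dict[str, list[tuple[int, int]]] = {}
                for b in blocks:
                    if b.label is not None:
                        spans.setdefault(b.label, []).append((pos, pos + len(b.seq)))
                    pos += len(b.seq)
                for ins_id, parts in spans.items():
                    truths[ins_id].loci[leaf] = Interval(
                        sid, min(s for s, _ in parts), max(e for _, e in parts), "+"
                    )
            assemblies[leaf] = GenomeAssembly(leaf, scaffolds)
            return
        # recurse into children in deterministic (preorder) order
        for child_branch, child_clade in _children_of(tree, clade):
            child_blocks = {
                sid: [_Block(b.label, b.seq, b.anc) for b in blocks]
                for sid, blocks in node_blocks.items()
            }
            evolve(child_blocks, child_branch, child_clade)

    root_clade = frozenset(tree.leaves)
    evolve(ancestor, None, root_clade)

    # every insertion is present in exactly the leaves descending from its branch
    truth_list = []
    for ins_id in sorted(truths):
        t = truths[ins_id]
        for leaf in tree.leaves:
            t.loci.setdefault(leaf, None)
        truth_list.append(t)
    return assemblies, truth_list


def _children_of(tree: SpeciesTree, clade: frozenset[str]):
    """Child (branch_id, clade) pairs of the node whose leaf set is ``clade``."""
    out = []
    for bid in tree.branch_ids:
        sub = tree.clade_of(bid)
        if sub < clade:
            parent = tree.parent_branch(bid)
            if parent is None:
                if clade == frozenset(tree.leaves):
                    out.append((bid, sub))
            elif tree.clade_of(parent) == clade:
                out.append((bid, sub))
    # deterministic order
    return sorted(out, key=lambda x: x[0])


# ---------------------------------------------------------------------------
# assembly fragmentation


def fragment_assembly(
    assembly: GenomeAssembly,
    target_n50: int,
    seed: int,
    return_map: bool = False,
):
    """Split scaffolds at random positions until N50 <= target.

    The longest scaffold is split at a uniform interior point each step;
    total sequence is conserved.  A target at or above the current N50 is a
    no-op.  With ``return_map`` the per-original-scaffold piece layout
    ``{orig_id: [(start, end, new_id), ...]}`` is returned alongside, so
    intervals can be remapped onto the fragmented assembly.
    """
    if target_n50 <= 0:
        raise ValueError("target N50 must be positive")
    current = assembly.scaffold_n50
    if target_n50 > current:
        raise ValueError(
            f"target N50 {target_n50} exceeds current N50 {current}"
        )
    rng = np.random.default_rng(seed)
    # piece: (name, seq, orig_id, orig_offset)
    pieces: list[tuple[str, str, str, int]] = [
        (name, seq, name, 0) for name, seq in assembly.scaffolds.items()
    ]
    counters: dict[str, int] = {}
    while compute_n50([len(p[1]) for p in pieces]) > target_n50:
        # split the longest piece
        idx = max(range(len(pieces)), key=lambda i: (len(pieces[i][1]), pieces[i][0]))
        name, seq, orig, off = pieces[idx]
        if len(seq) < 2:
            break
        cut = int(rng.integers(1, len(seq)))
        counters[orig] = counters.get(orig, 0) + 2
        a = (f"{orig}_f{counters[orig] - 1}", seq[:cut], orig, off)
        b = (f"{orig}_f{counters[orig]}", seq[cut:], orig, off + cut)
        pieces[idx : idx + 1] = [a, b]
    out = GenomeAssembly(assembly.species_id, {p[0]: p[1] for p in pieces})
    if not return_map:
        return out
    layout: dict[str, list[tuple[int, int, str]]] = {}
    for name, seq, orig, off in pieces:
        layout.setdefault(orig, []).append((off, off + len(seq), name))
    for spans in layout.values():
        spans.sort()
    return out, layout


def remap_interval(interval: Interval, layout: dict[str, list[tuple[int, int, str]]]) -> Interval | None:
    """Map an interval onto a fragmented assembly; None if a break cuts it."""
    for start, end, new_id in layout.get(interval.scaffold_id, ()):
        if start <= interval.start and interval.end <= end:
            return Interval(new_id, interval.start - start, interval.end - start, interval.strand)
    return None
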