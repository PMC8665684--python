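"""Homology search and repeat-library construction.

The search is a deterministic seed-and-extend local aligner: exact k-mer
seeds (2-bit encoded, binary-searched against a per-scaffold sorted index)
are clustered into diagonal bands, and each band is extended by exact local
dynamic programming over a padded window.  Both strands are searched.  The
output contract mirrors the 12-column tabular dialect so an external search
tool can be swapped in via ``io_formats.read_tabular_hits``.

On top of the search sit the iterative library-expansion loop (search,
2,700 bp filter, 3'-anchor and EN+RT checks, clustering, repeat until the
number of distinct full-length copies stops growing), greedy centroid
clustering at a global-identity threshold, and reciprocal-best-hit family
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anatomy
from .dna import kmer_codes, revcomp
from .io_formats import AlignmentHit, GenomeAssembly, Interval
from .pairwise import (
    global_align_stats,
    local_align,
    local_align_split,
    make_global_aligner,
    make_local_aligner,
)

__all__ = [
    "SearchParams",
    "RepeatLibrary",
    "KmerIndex",
    "search",
    "chain_hits",
    "cluster_centroids",
    "iterative_expand",
    "assign_family",
]


@dataclass(frozen=True)
class SearchParams:
    """Parameters of the internal seed-and-extend nucleotide search."""

    word_size: int = 11
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_hit_length: int = 50
    min_identity: float = 75.0
    # significance floor on the raw alignment score, playing the role of a
    # BLAST e-value cutoff: for match/mismatch +2/-3 a random 1.7 kb x 1 Mb
    # comparison produces score >= 50 hits with probability ~1e-5
    min_score: float = 50.0
    diagonal_band: int = 75  # max diagonal drift within one seed cluster
    max_seed_gap: int = 700  # max subject-position gap within one cluster
    extension_pad: int = 75  # window padding around a seed cluster
    max_internal_gap: int = 30  # alignments are split into hits at longer gaps
    max_kmer_frequency: int = 200  # seeds more frequent than this are skipped
    min_cluster_seeds: int = 2  # two-hit rule: lone chance seeds are not extended
    min_cluster_span: int = 15  # seeds must cover this much of the query axis
    max_candidates: int = 200  # extension windows per (scaffold, strand)


@dataclass
class RepeatLibrary:
    """A named repeat library: label -> consensus/centroid sequence."""

    entries: dict[str, str]
    provenance: str = "bundled_reference"  # bundled_reference | centroid | curated
    member_counts: dict[str, int] = field(default_factory=dict)
    memberships: dict[str, str] = field(default_factory=dict)  # member label -> centroid

    def __post_init__(self) -> None:
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate library labels")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Sorted exact k-mer index over all scaffolds of an assembly."""

    def __init__(self, assembly: GenomeAssembly, k: int = 11):
        self.assembly = assembly
        self.k = k
        self.scaffold_ids = list(assembly.scaffolds)
        self._sorted_codes: dict[str, np.ndarray] = {}
        self._sorted_pos: dict[str, np.ndarray] = {}
        for sid in self.scaffold_ids:
            codes = kmer_codes(assembly.scaffolds[sid], k)
            valid = codes >= 0
            codes = codes[valid]
            pos = np.nonzero(valid)[0]
            order = np.argsort(codes, kind="stable")
            self._sorted_codes[sid] = codes[order]
            self._sorted_pos[sid] = pos[order]

    def seed_matches(
        self, query: str, max_freq: int, qmask: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Per scaffold: array of (query_pos, subject_pos) seed pairs.

        ``qmask``: optional boolean array over query k-mer start positions;
        positions set False do not seed (hits overlapping masked-only
        regions must be found through neighbouring unmasked seeds).
        """
        qcodes = kmer_codes(query, self.k)
        if qmask is not None:
            qcodes = np.where(qmask[: len(qcodes)], qcodes, -1)
        qvalid = np.nonzero(qcodes >= 0)[0]
        out: dict[str, np.ndarray] = {}
        for sid in self.scaffold_ids:
            codes = self._sorted_codes[sid]
            pos = self._sorted_pos[sid]
            if len(codes) == 0 or len(qvalid) == 0:
                continue
            qc = qcodes[qvalid]
            left = np.searchsorted(codes, qc, side="left")
            right = np.searchsorted(codes, qc, side="right")
            counts = right - left
            keep = (counts > 0) & (counts <= max_freq)
            if not keep.any():
                continue
            c = counts[keep]
            l = left[keep]
            total = int(c.sum())
            starts = np.cumsum(c) - c
            within = np.arange(total) - np.repeat(starts, c)
            spos = pos[np.repeat(l, c) + within]
            qpos = np.repeat(qvalid[keep], c)
            out[sid] = np.column_stack([qpos, spos])
        return out


# ---------------------------------------------------------------------------
# search


def _cluster_seeds(pairs: np.ndarray, band: int, max_gap: int) -> list[tuple[int, int, int, int]]:
    """Group (qpos, spos) seed pairs into diagonal clusters.

    Returns (qlo, qhi, slo, shi) per cluster (positions of seed starts).
    """
    diag = pairs[:, 1] - pairs[:, 0]
    order = np.lexsort((pairs[:, 1], diag))
    diag = diag[order]
    pairs = pairs[order]
    # band boundaries on the diagonal axis
    band_breaks = np.flatnonzero(np.diff(diag) > band) + 1
    clusters: list[tuple[int, int, int, int]] = []
    for chunk in np.split(pairs, band_breaks):
        # within a diagonal band, split on subject-position gaps
        sorder = np.argsort(chunk[:, 1], kind="stable")
        chunk = chunk[sorder]
        gap_breaks = np.flatnonzero(np.diff(chunk[:, 1]) > max_gap) + 1
        bounds = np.concatenate(([0], gap_breaks, [len(chunk)]))
        starts = bounds[:-1]
        q = chunk[:, 0]
        s = chunk[:, 1]
        qmin = np.minimum.reduceat(q, starts)
        qmax = np.maximum.reduceat(q, starts)
        smin = s[starts]
        smax = s[bounds[1:] - 1]
        sizes = bounds[1:] - starts
        for a, b, c, d, n in zip(qmin, qmax, smin, smax, sizes):
            clusters.append((int(a), int(b), int(c), int(d), int(n)))
    return clusters


def search(
    library: RepeatLibrary | dict[str, str],
    assembly: GenomeAssembly,
    params: SearchParams = SearchParams(),
    index: KmerIndex | None = None,
    keep_cluster=None,
    seed_query_ranges: list[tuple[int, int]] | None = None,
) -> list[AlignmentHit]:
    """Search every library entry against an assembly on both strands.

    Deterministic: hits are sorted by (query, scaffold, start, strand).

    ``keep_cluster``: optional predicate ``f(reach_lo, reach_hi) -> bool``
    over the query interval (original query axis) that an extension window
    could possibly cover; clusters for which it returns False are skipped.
    Because a windowed alignment can never leave its window, a predicate
    that encodes "could this hit survive downstream coordinate filters"
    prunes extensions without changing the surviving hit set.

    ``seed_query_ranges``: optional query intervals (original axis) whose
    k-mers are allowed to seed; others are skipped.  Alignments still
    extend freely across unseeded regions.
    """
    entries = library.entries if isinstance(library, RepeatLibrary) else library
    if not entries:
        raise ValueError("empty library")
    if index is None:
        index = KmerIndex(assembly, params.word_size)
    elif index.k != params.word_size:
        raise ValueError("index word size does not match search params")
    aligner = make_local_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    hits: list[AlignmentHit] = []
    for label in entries:
        hits.extend(
            _search_one(
                label, entries[label], index, params, aligner, keep_cluster,
                seed_query_ranges,
            )
        )
    hits.sort(
        key=lambda h: (
            h.query_id,
            h.subject_interval.scaffold_id,
            h.subject_interval.start,
            h.subject_interval.strand,
            h.query_start,
        )
    )
    return hits


def _search_one(
    label, query, index, params, aligner, keep_cluster=None, seed_query_ranges=None
) -> list[AlignmentHit]:
    qlen = len(query)
    base_mask = None
    if seed_query_ranges is not None:
        base_mask = np.zeros(qlen, dtype=bool)
        for lo, hi in seed_query_ranges:
            base_mask[max(0, lo) : min(qlen, hi)] = True
    out: list[AlignmentHit] = []
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        if base_mask is None:
            qmask = None
        elif strand == "+":
            qmask = base_mask
        else:
            # oriented k-mer start p covers original [qlen-p-k, qlen-p)
            k = params.word_size
            qmask = base_mask[::-1].copy()
            qmask = np.roll(qmask, -(k - 1))
        matches = index.seed_matches(q, params.max_kmer_frequency, qmask)
        for sid, pairs in matches.items():
            subject = index.assembly.scaffolds[sid]
            clusters = [
                c
                for c in _cluster_seeds(pairs, params.diagonal_band, params.max_seed_gap)
                if c[4] >= params.min_cluster_seeds
                and c[1] - c[0] >= params.min_cluster_span
            ]
            if len(clusters) > params.max_candidates:
                # keep the widest clusters (deterministic order)
                clusters.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
                clusters = clusters[: params.max_candidates]
            seen_windows: set[tuple[int, int, int, int]] = set()
            for qlo, qhi, slo, shi, _nseeds in clusters:
                k = params.word_size
                pad = params.extension_pad
                qa = max(0, qlo - pad)
                qb = min(qlen, qhi + k + pad)
                if keep_cluster is not None:
                    if strand == "+":
                        reach_lo, reach_hi = qa, qb
                    else:
                        reach_lo, reach_hi = qlen - qb, qlen - qa
                    if not keep_cluster(reach_lo, reach_hi):
                        continue
                sa = max(0, slo - pad)
                sb = min(len(subject), shi + k + pad)
                key = (qa, qb, sa, sb)
                if key in seen_windows:
                    continue
                seen_windows.add(key)
                seg_stats = local_align_split(
                    subject[sa:sb], q[qa:qb], aligner, params.max_internal_gap
                )
                for stats in seg_stats:
                    if stats.columns < params.min_hit_length:
                        continue
                    if stats.identity < params.min_identity:
                        continue
                    if stats.score < params.min_score:
                        continue
                    s0 = sa + stats.subject_start
                    s1 = sa + stats.subject_end
                    if strand == "+":
                        q0, q1 = qa + stats.query_start, qa + stats.query_end
                    else:
                        q0 = qlen - (qa + stats.query_end)
                        q1 = qlen - (qa + stats.query_start)
                    out.append(
                        AlignmentHit(
                            query_id=label,
                            subject_interval=Interval(sid, s0, s1, strand),
                            query_start=q0,
                            query_end=q1,
                            percent_identity=float(round(stats.identity, 3)),
                            aligned_length=int(stats.columns),
                            mismatches=int(stats.mismatches),
                            gap_openings=int(stats.gap_openings),
                            score=float(stats.score),
                        )
                    )
    return _dedupe_hits(out)


def _dedupe_hits(hits: list[AlignmentHit], min_frac: float = 0.9) -> list[AlignmentHit]:
    """Drop hits nearly contained in a higher-scoring hit (same scaffold+strand)."""
    hits = sorted(
        hits,
        key=lambda h: (-h.score, h.subject_interval.scaffold_id, h.subject_interval.start, h.query_start),
    )
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = False
        for k in kept:
            if (
                k.subject_interval.scaffold_id == h.subject_interval.scaffold_id
                and k.subject_interval.strand == h.subject_interval.strand
            ):
                ov = k.subject_interval.overlap(h.subject_interval)
                if ov >= min_frac * h.subject_interval.length:
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    return kept


def chain_hits(
    hits: list[AlignmentHit],
    max_gap: int = 50,
    max_overlap: int = 20,
    max_links: int | None = None,
) -> list[AlignmentHit]:
    """Chain collinear same-strand hits of the same query on one scaffold.

    Two hits chain when both the query-axis and subject-axis gaps between
    them are <= ``max_gap`` (small overlaps up to ``max_overlap`` are
    allowed) and their order is consistent with the strand.  ``max_links``
    bounds the number of sub-hits per chain (None = unbounded).
    """
    groups: dict[tuple[str, str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault(
            (h.query_id, h.subject_interval.scaffold_id, h.subject_interval.strand), []
        ).append(h)
    out: list[AlignmentHit] = []
    for (_, sid, strand), ghits in sorted(groups.items()):
        ghits = sorted(ghits, key=lambda h: (h.subject_interval.start, h.query_start))
        chain: list[AlignmentHit] = []
        nlinks = 1
        for h in ghits:
            if not chain:
                chain, nlinks = [h], 1
                continue
            prev = chain[-1]
            sgap = h.subject_interval.start - prev.subject_interval.end
            if strand == "+":
                qgap = h.query_start - prev.query_end
            else:
                qgap = prev.query_start - h.query_end
            linkable = (
                -max_overlap <= sgap <= max_gap
                and -max_overlap <= qgap <= max_gap
                and (max_links is None or nlinks < max_links)
            )
            if linkable:
                chain.append(h)
                nlinks += 1
            else:
                out.append(_merge_chain(chain))
                chain, nlinks = [h], 1
        if chain:
            out.append(_merge_chain(chain))
    out.sort(
        key=lambda h: (
            h.query_id,
            h.subject_interval.scaffold_id,
            h.subject_interval.start,
            h.subject_interval.strand,
        )
    )
    return out


def _merge_chain(chain: list[AlignmentHit]) -> AlignmentHit:
    if len(chain) == 1:
        return chain[0]
    first = chain[0]
    iv = Interval(
        first.subject_interval.scaffold_id,
        min(h.subject_interval.start for h in chain),
        max(h.subject_interval.end for h in chain),
        first.subject_interval.strand,
    )
    total_cols = sum(h.aligned_length for h in chain)
    matches = sum(round(h.percent_identity / 100.0 * h.aligned_length) for h in chain)
    return AlignmentHit(
        query_id=first.query_id,
        subject_interval=iv,
        query_start=min(h.query_start for h in chain),
        query_end=max(h.query_end for h in chain),
        percent_identity=round(100.0 * matches / total_cols, 3),
        aligned_length=total_cols,
        mismatches=sum(h.mismatches for h in chain),
        gap_openings=sum(h.gap_openings for h in chain) + len(chain) - 1,
        score=sum(h.score for h in chain),
    )


# ---------------------------------------------------------------------------
# clustering


def cluster_centroids(
    sequences: dict[str, str],
    identity_threshold: float = 0.9,
) -> RepeatLibrary:
    """Greedy length-sorted centroid clustering.

    Sequences are processed longest first (ties broken lexicographically by
    label); each joins the first centroid it matches at >= the threshold
    (global identity with free end gaps, internal gaps counted), otherwise
    it founds a new cluster.  The centroid is the founding (longest) member.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    aligner = make_global_aligner()
    order = sorted(sequences, key=lambda lab: (-len(sequences[lab]), lab))
    centroids: list[str] = []
    entries: dict[str, str] = {}
    counts: dict[str, int] = {}
    memberships: dict[str, str] = {}
    for label in order:
        seq = sequences[label]
        home = None
        for c in centroids:
            stats = global_align_stats(entries[c], seq, aligner)
            if stats is not None and stats.columns > 0:
                if stats.matches / stats.columns >= identity_threshold:
                    home = c
                    break
        if home is None:
            centroids.append(label)
            entries[label] = seq
            counts[label] = 1
            memberships[label] = label
        else:
            counts[home] += 1
            memberships[label] = home
    return RepeatLibrary(
        entries=entries, provenance="centroid", member_counts=counts, memberships=memberships
    )


# ---------------------------------------------------------------------------
# iterative expansion


@dataclass
class _Locus:
    species: str
    interval: Interval
    sequence: str  # element sense strand


def _reciprocal_overlap(a: Interval, b: Interval, frac: float = 0.8) -> bool:
    ov = a.overlap(b)
    return ov >= frac * a.length and ov >= frac * b.length


def iterative_expand(
    initial_library: RepeatLibrary,
    assemblies: dict[str, GenomeAssembly],
    params: SearchParams = SearchParams(),
    min_element_bp: int = 2700,
    cluster_identity: float = 0.9,
    max_rounds: int = 20,
    anatomy_kwargs: dict | None = None,
) -> tuple[RepeatLibrary, list[int]]:
    """Iterative repeat-library expansion to convergence.

    Each round searches every assembly with the current library, keeps
    chained hits >= ``min_element_bp`` whose extracted sequence is
    3'-anchored, retains those with EN+RT evidence as full-length, clusters
    the accumulated full-length set together with the previous round's
    centroids, and feeds centroids plus the initial library into the next
    round.  Convergence: the number of distinct full-length loci
    (deduplicated at >= 80% reciprocal overlap) did not increase.

    Returns the final library and the per-round locus counts.
    """
    if len(initial_library) == 0:
        raise ValueError("initial library is empty")
    indexes = {sp: KmerIndex(asm, params.word_size) for sp, asm in assemblies.items()}
    library = RepeatLibrary(dict(initial_library.entries), provenance=initial_library.provenance)
    prev_centroids: dict[str, str] = {}
    loci: list[_Locus] = []
    counts_per_round: list[int] = []
    anatomy_kwargs = anatomy_kwargs or {}
    for round_no in range(1, max_rounds + 1):
        for sp in sorted(assemblies):
            asm = assemblies[sp]
            hits = search(library, asm, params, index=indexes[sp])
            chained = chain_hits(hits)
            for h in chained:
                iv = h.subject_interval
                if iv.length < min_element_bp:
                    continue
                if any(
                    l.species == sp and _reciprocal_overlap(l.interval, iv)
                    for l in loci
                ):
                    continue
                seq = asm.fetch(iv)
                if iv.strand == "-":
                    seq = revcomp(seq)
                copy = anatomy.analyze_sequence(
                    f"{sp}:{iv.scaffold_id}:{iv.start}-{iv.end}", seq, locus=iv,
                    **anatomy_kwargs,
                )
                if copy.status in ("full_length", "intact"):
                    loci.append(_Locus(species=sp, interval=iv, sequence=seq))
        counts_per_round.append(len(loci))
        if round_no > 1 and counts_per_round[-1] <= counts_per_round[-2]:
            return library, counts_per_round
        if round_no == 1 and not loci:
            # nothing found at all: the initial library is already the fixed point
            return library, counts_per_round
        to_cluster = {
            f"locus{idx:05d}_{l.species}": l.sequence for idx, l in enumerate(loci)
        }
        to_cluster.update(prev_centroids)
        clustered = cluster_centroids(to_cluster, cluster_identity)
        prev_centroids = {
            f"centroid{idx:04d}": seq
            for idx, (_, seq) in enumerate(sorted(clustered.entries.items()))
        }
        entries = dict(prev_centroids)
        for lab, seq in initial_library.entries.items():
            entries.setdefault(lab, seq)
        library = RepeatLibrary(entries, provenance="centroid")
    raise RuntimeError(
        f"library expansion did not converge after {max_rounds} rounds; "
        f"per-round full-length locus counts: {counts_per_round}"
    )


# ---------------------------------------------------------------------------
# family assignment


def assign_family(
    copy_seq: str,
    reference_library: RepeatLibrary,
    params: SearchParams = SearchParams(),
) -> str:
    """Reciprocal-best-hit family assignment against a named library.

    The copy's best-scoring library entry wins, confirmed by the reciprocal
    alignment meeting the identity floor; ties break by higher identity,
    then lexicographic label.  Returns ``"unassigned"`` when no entry
    reaches the identity/length floor.
    """
    if not copy_seq:
        return "unassigned"
    aligner = make_local_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    best: tuple[float, float, str] | None = None  # (-score, -identity, label)
    for label in sorted(reference_library.entries):
        ref = reference_library.entries[label]
        stats = local_align(ref, copy_seq, aligner)
        if stats is None or stats.columns < params.min_hit_length:
            continue
        if stats.identity < params.min_identity:
            continue
        key = (-stats.score, -stats.identity, label)
        if best is None or key < best:
            best = key
    if best is None:
        return "unassigned"
    label = best[2]
    # reciprocal confirmation: the reference finds the copy back
    stats = local_align(copy_seq, reference_library.entries[label], aligner)
    if stats is None or stats.identity < params.min_identity or stats.columns < params.min_hit_length:
        return "unassigned"
    return label
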