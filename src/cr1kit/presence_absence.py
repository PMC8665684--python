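"""Flank-anchored presence/absence scoring of CR1 insertion loci.

Each 3'-anchored CR1 copy of 100–600 bp in a focal species, at least
600 bp from any contig end and with clean (<= 25% N) 600 bp flanks, is
turned into a locus query (5' flank + CR1 + 3' flank).  The query is
searched against each related species and scored through a fixed
elimination cascade; whenever orthology cannot be resolved cleanly the
locus is called unscorable rather than risking misclassifying deletions
or segmental duplications as insertion events:

1. any single contiguous hit covering the entire repeat plus >= 150 bp of
   each flank -> shared (FULL_SPAN);
2. hits whose outer query coordinate reaches less than 150 bp beyond the
   CR1/flank boundary are discarded (paralogous-CR1 / microsatellite
   guard);
3. the survivors must yield exactly one 5'-flank and one 3'-flank anchor,
   in the same orientation on the same target scaffold (more than one
   anchor for either flank -> MULTI_HIT; fewer than two usable anchors
   -> NO_ANCHOR);
4. if the two flank anchors sit within 16 bp of each other in the target
   and the un-aligned query residue is about the CR1 length -> absent
   (CLEAN_PREINSERTION_SITE); a microsatellite array inside the target
   gap is tolerated without penalty;
5. if the target gap is about the same as the query gap between the
   anchors -> shared (GAPPED_SHARED);
6. anything else -> unscorable (AMBIGUOUS_GAP).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anatomy import BUILTIN_MOTIFS, CR1Copy, detect_microsatellite
from .homology import KmerIndex, SearchParams, chain_hits, search
from .io_formats import AlignmentHit, GenomeAssembly, Interval

__all__ = [
    "LocusQuery",
    "LocusCall",
    "CascadeParams",
    "CALLS",
    "REASONS",
    "select_candidates",
    "score_locus",
    "sweep_boundary_param",
    "PresenceAbsenceScorer",
]

CALLS = ("shared", "absent", "unscorable")
REASONS = (
    "FULL_SPAN",
    "MULTI_HIT",
    "NO_ANCHOR",
    "CLEAN_PREINSERTION_SITE",
    "GAPPED_SHARED",
    "AMBIGUOUS_GAP",
)


@dataclass(frozen=True)
class CascadeParams:
    """All thresholds of the elimination cascade (defaults as published)."""

    flank_bp: int = 600
    min_cr1_bp: int = 100
    max_cr1_bp: int = 600
    min_edge_distance_bp: int = 600
    max_flank_n_fraction: float = 0.25  # strictly-more-than discards
    boundary_bp: int = 150  # step-2/3 outer-coordinate distance
    max_clean_gap_bp: int = 16
    min_full_span_flank_bp: int = 150
    chain_gap_bp: int = 50
    length_tol_floor_bp: int = 16
    length_tol_fraction: float = 0.10

    def length_tol(self, cr1_length: int) -> int:
        """'Near the same length': max(16 bp, 10% of the CR1 length)."""
        return max(self.length_tol_floor_bp, int(round(self.length_tol_fraction * cr1_length)))


@dataclass(frozen=True)
class LocusQuery:
    insertion_id: str
    focal_species: str
    cr1_interval: Interval
    cr1_length: int
    flank5: str
    flank3: str
    query_seq: str  # flank5 + CR1 + flank3, scaffold plus strand
    family_id: str = "unassigned"
    cr1_strand: str = "+"  # element orientation on the scaffold


@dataclass(frozen=True)
class LocusCall:
    insertion_id: str
    target_species: str
    call: str
    reason: str
    target_gap: int | None = None

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


# ---------------------------------------------------------------------------
# candidate selection


def select_candidates(
    copies: list[CR1Copy],
    assembly: GenomeAssembly,
    params: CascadeParams = CascadeParams(),
) -> tuple[list[LocusQuery], list[tuple[str, str]]]:
    """Filter 3'-anchored copies into locus queries; log exclusions.

    Rules: CR1 length within [100, 600]; at least 600 bp from either
    contig end; each 600 bp flank at most 25% N (strictly more discards).
    """
    queries: list[LocusQuery] = []
    excluded: list[tuple[str, str]] = []
    for copy in copies:
        if copy.locus is None:
            excluded.append((copy.copy_id, "no locus"))
            continue
        iv = copy.locus
        length = iv.length
        if not (params.min_cr1_bp <= length <= params.max_cr1_bp):
            excluded.append((copy.copy_id, f"size window ({length} bp)"))
            continue
        scaffold_len = len(assembly.scaffolds[iv.scaffold_id])
        if iv.start < params.min_edge_distance_bp or scaffold_len - iv.end < params.min_edge_distance_bp:
            excluded.append((copy.copy_id, "contig edge rule"))
            continue
        flank5 = assembly.scaffolds[iv.scaffold_id][iv.start - params.flank_bp : iv.start]
        flank3 = assembly.scaffolds[iv.scaffold_id][iv.end : iv.end + params.flank_bp]
        limit = params.max_flank_n_fraction * params.flank_bp
        if flank5.count("N") > limit or flank3.count("N") > limit:
            excluded.append((copy.copy_id, "flank N fraction"))
            continue
        cr1_seq = assembly.fetch(iv)
        queries.append(
            LocusQuery(
                insertion_id=copy.copy_id,
                focal_species=assembly.species_id,
                cr1_interval=iv,
                cr1_length=length,
                flank5=flank5,
                flank3=flank3,
                query_seq=flank5 + cr1_seq + flank3,
                family_id=copy.family_id,
                cr1_strand=iv.strand,
            )
        )
    return queries, excluded


# ---------------------------------------------------------------------------
# the cascade


def _anchors(
    hits: list[AlignmentHit], query: LocusQuery, boundary: int, params: CascadeParams
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Classify surviving hits as 5'- or 3'-flank anchors.

    A 5' anchor reaches at least ``boundary`` bp into the 5' flank beyond
    the flank/CR1 junction (outer query coordinate <= flank - boundary);
    mirrored for the 3' anchor.
    """
    f = params.flank_bp
    cr1_end = f + query.cr1_length
    fives, threes = [], []
    for h in hits:
        if h.query_start <= f - boundary and h.query_end <= cr1_end + boundary:
            fives.append(h)
        elif h.query_end >= cr1_end + boundary and h.query_start >= f - boundary:
            threes.append(h)
        # hits spanning both boundaries were already handled as FULL_SPAN
    return fives, threes


def _cascade(
    query: LocusQuery,
    raw_hits: list[AlignmentHit],
    target: GenomeAssembly,
    params: CascadeParams,
    boundary: int | None = None,
) -> LocusCall:
    boundary = params.boundary_bp if boundary is None else boundary
    f = params.flank_bp
    L = query.cr1_length
    cr1_end = f + L
    mk = lambda call, reason, gap=None: LocusCall(
        insertion_id=query.insertion_id,
        target_species=target.species_id,
        call=call,
        reason=reason,
        target_gap=gap,
    )
    # (2) full span: a single contiguous hit covering the CR1 and >=150 bp of each flank
    for h in raw_hits:
        if (
            h.query_start <= f - params.min_full_span_flank_bp
            and h.query_end >= cr1_end + params.min_full_span_flank_bp
        ):
            return mk("shared", "FULL_SPAN")
    # chain fragmented flank alignments (<= 2 collinear sub-hits, <= 50 bp apart)
    chained = chain_hits(raw_hits, max_gap=params.chain_gap_bp, max_links=2)
    # re-check full span on chains is deliberately NOT done: a shared call
    # via step 1 requires one contiguous alignment (stricter).
    # (3) boundary discard + anchor classification
    fives, threes = _anchors(chained, query, boundary, params)
    if len(fives) > 1 or len(threes) > 1:
        return mk("unscorable", "MULTI_HIT")
    if not fives or not threes:
        return mk("unscorable", "NO_ANCHOR")
    h5, h3 = fives[0], threes[0]
    iv5, iv3 = h5.subject_interval, h3.subject_interval
    if iv5.scaffold_id != iv3.scaffold_id or iv5.strand != iv3.strand:
        return mk("unscorable", "NO_ANCHOR")
    # (5) gaps
    if iv5.strand == "+":
        raw_gap = iv3.start - iv5.end
        gap_lo, gap_hi = iv5.end, iv3.start
    else:
        raw_gap = iv5.start - iv3.end
        gap_lo, gap_hi = iv3.end, iv5.start
    gap = max(0, raw_gap)  # anchor overlap (e.g. over the TSD) counts as adjacency
    covered5 = min(max(h5.query_end - f, 0), L)
    covered3 = min(max(cr1_end - h3.query_start, 0), L)
    residual = max(0, L - covered5 - covered3)
    expected_shared_gap = max(0, h3.query_start - h5.query_end)
    tol = params.length_tol(L)
    # (6) clean pre-insertion site; tolerate a microsatellite array in the gap
    effective_gap = gap
    if gap > params.max_clean_gap_bp and gap_hi > gap_lo:
        gap_seq = target.scaffolds[iv5.scaffold_id][gap_lo:gap_hi]
        try:
            ms = detect_microsatellite(gap_seq, BUILTIN_MOTIFS, search_window_bp=len(gap_seq))
        except ValueError:
            ms = None
        if ms is not None:
            _, (ms_start, ms_end) = ms
            effective_gap = gap - (ms_end - ms_start)
    if effective_gap <= params.max_clean_gap_bp and abs(residual - L) <= tol:
        return mk("absent", "CLEAN_PREINSERTION_SITE", gap=raw_gap)
    # (7) gap consistent with the insertion being present
    if abs(gap - expected_shared_gap) <= tol:
        return mk("shared", "GAPPED_SHARED", gap=raw_gap)
    # (8)
    return mk("unscorable", "AMBIGUOUS_GAP", gap=raw_gap)


def _flank_seed_ranges(query: LocusQuery, params: CascadeParams) -> list[tuple[int, int]]:
    """Seed only from the flanks: every hit the cascade can use overlaps a
    flank, and alignments still extend across the repeat interior."""
    f = params.flank_bp
    qlen = 2 * f + query.cr1_length
    return [(0, f), (f + query.cr1_length, qlen)]


def _keep_cluster_predicate(query: LocusQuery, params: CascadeParams, min_boundary: int):
    """Prune search extensions that cannot survive the coordinate filters.

    A hit can matter only if it reaches at least ``min_boundary`` bp into a
    flank (anchor rules) or could span the repeat with both flanks; a
    windowed extension can never leave its window, so clusters whose
    reachable query span stays inside the CR1 interior are skipped exactly.
    """
    b = min(min_boundary, params.min_full_span_flank_bp)
    left_limit = params.flank_bp - b
    right_limit = params.flank_bp + query.cr1_length + b
    return lambda lo, hi: lo <= left_limit or hi >= right_limit


def score_locus(
    query: LocusQuery,
    target: GenomeAssembly,
    search_params: SearchParams = SearchParams(),
    cascade_params: CascadeParams = CascadeParams(),
    index: KmerIndex | None = None,
) -> LocusCall:
    """Score one locus query in one target species."""
    hits = search(
        {query.insertion_id: query.query_seq},
        target,
        search_params,
        index=index,
        keep_cluster=_keep_cluster_predicate(query, cascade_params, cascade_params.boundary_bp),
        seed_query_ranges=_flank_seed_ranges(query, cascade_params),
    )
    return _cascade(query, hits, target, cascade_params)


def sweep_boundary_param(
    queries: list[LocusQuery],
    target: GenomeAssembly,
    distances: list[int],
    search_params: SearchParams = SearchParams(),
    cascade_params: CascadeParams = CascadeParams(),
    index: KmerIndex | None = None,
) -> pd.DataFrame:
    """Re-run the boundary-discard step over a range of distances.

    One search per query; the cascade is replayed per distance.  Returns
    call and reason counts per distance (rows sorted by distance).
    """
    if not distances:
        raise ValueError("distance list must be non-empty")
    if index is None:
        index = KmerIndex(target, search_params.word_size)
    min_d = min(distances)
    cached = [
        (
            q,
            search(
                {q.insertion_id: q.query_seq},
                target,
                search_params,
                index=index,
                keep_cluster=_keep_cluster_predicate(q, cascade_params, min_d),
                seed_query_ranges=_flank_seed_ranges(q, cascade_params),
            ),
        )
        for q in queries
    ]
    rows = []
    for d in sorted(distances):
        counts = {c: 0 for c in CALLS}
        reasons = {r: 0 for r in REASONS}
        for q, hits in cached:
            call = _cascade(q, hits, target, cascade_params, boundary=d)
            counts[call.call] += 1
            reasons[call.reason] += 1
        rows.append({"boundary_bp": d, **counts, **reasons})
    return pd.DataFrame(rows)


class PresenceAbsenceScorer:
    """Scores many loci against many targets with cached k-mer indexes."""

    def __init__(
        self,
        assemblies: dict[str, GenomeAssembly],
        search_params: SearchParams = SearchParams(),
        cascade_params: CascadeParams = CascadeParams(),
    ):
        self.assemblies = assemblies
        self.search_params = search_params
        self.cascade_params = cascade_params
        self._indexes: dict[str, KmerIndex] = {}

    def _index(self, species: str) -> KmerIndex:
        if species not in self.assemblies:
            raise KeyError(f"target species {species!r} not in assembly set")
        if species not in self._indexes:
            self._indexes[species] = KmerIndex(
                self.assemblies[species], self.search_params.word_size
            )
        return self._indexes[species]

    def score(self, query: LocusQuery, target_species: str) -> LocusCall:
        return score_locus(
            query,
            self.assemblies[target_species],
            self.search_params,
            self.cascade_params,
            index=self._index(target_species),
        )

    def score_all(
        self, queries: list[LocusQuery], target_species: list[str]
    ) -> list[LocusCall]:
        calls = []
        for q in queries:
            for sp in target_species:
                if sp == q.focal_species:
                    continue
                calls.append(self.score(q, sp))
        return calls
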