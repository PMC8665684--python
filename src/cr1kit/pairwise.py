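"""Pairwise alignment helpers shared by the search, clustering and divergence stages.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` that return explicit
coordinate/identity statistics instead of alignment objects, so downstream
code never has to re-derive block structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = [
    "AlignmentStats",
    "make_local_aligner",
    "make_global_aligner",
    "make_protein_aligner",
    "local_align",
    "local_align_split",
    "global_align_stats",
    "global_identity",
]


@dataclass(frozen=True)
class AlignmentStats:
    """Coordinate and identity summary of one pairwise alignment.

    Coordinates are 0-based half-open; ``subject`` is the first sequence
    passed to the aligner (the "target" in Biopython terms).
    """

    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    matches: int
    mismatches: int
    columns: int  # aligned columns including internal gap columns
    gap_openings: int
    score: float

    @property
    def identity(self) -> float:
        """Percent identity over aligned columns (gaps count as columns)."""
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns

    @property
    def aligned_sites(self) -> int:
        """Gap-free aligned columns (matches + mismatches)."""
        return self.matches + self.mismatches


def make_local_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def make_global_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Align.PairwiseAligner:
    """Global aligner with free end gaps (both sequences).

    This is the convention used for clustering identity and per-copy
    divergence: 5'-truncated copies should not be penalised for the
    consensus overhang.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def make_protein_aligner(
    match: float = 1.0,
    mismatch: float = -0.5,
    gap_open: float = -3.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Identity-scored local protein aligner.

    The mild mismatch penalty keeps local alignments from clipping
    moderately diverged marker ends, so a coverage threshold measures the
    real extent of homology rather than the best-scoring core.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _block_stats(subject: str, query: str, alignment) -> AlignmentStats:
    """Walk the aligned blocks of a Biopython alignment and tally columns."""
    sub_blocks, qry_blocks = alignment.aligned
    if len(sub_blocks) == 0:
        return AlignmentStats(0, 0, 0, 0, 0, 0, 0, 0, float(alignment.score))
    matches = 0
    mismatches = 0
    columns = 0
    gap_openings = 0
    prev_s_end = None
    prev_q_end = None
    for (s0, s1), (q0, q1) in zip(sub_blocks, qry_blocks):
        if prev_s_end is not None:
            ds = s0 - prev_s_end
            dq = q0 - prev_q_end
            columns += max(ds, dq)
            if ds > 0:
                gap_openings += 1
            if dq > 0:
                gap_openings += 1
        a = np.frombuffer(subject[s0:s1].encode(), dtype=np.uint8)
        b = np.frombuffer(query[q0:q1].encode(), dtype=np.uint8)
        eq = int((a == b).sum())
        matches += eq
        mismatches += (s1 - s0) - eq
        columns += s1 - s0
        prev_s_end, prev_q_end = s1, q1
    return AlignmentStats(
        subject_start=int(sub_blocks[0][0]),
        subject_end=int(sub_blocks[-1][1]),
        query_start=int(qry_blocks[0][0]),
        query_end=int(qry_blocks[-1][1]),
        matches=matches,
        mismatches=mismatches,
        columns=columns,
        gap_openings=gap_openings,
        score=float(alignment.score),
    )


def split_blocks_stats(
    subject: str, query: str, alignment, max_internal_gap: int
) -> list[AlignmentStats]:
    """Split one alignment into segments at internal gaps > ``max_internal_gap``.

    Cheap gap extension lets a single local alignment bridge a long
    insertion/deletion (e.g. an entire repeat missing from the subject);
    a hit-oriented caller wants such an alignment reported as separate
    local hits, as a seed-and-extend search tool would.
    """
    sub_blocks, qry_blocks = alignment.aligned
    if len(sub_blocks) == 0:
        return []
    segments: list[tuple[int, int]] = []
    seg_start = 0
    for i in range(1, len(sub_blocks)):
        ds = sub_blocks[i][0] - sub_blocks[i - 1][1]
        dq = qry_blocks[i][0] - qry_blocks[i - 1][1]
        if max(ds, dq) > max_internal_gap:
            segments.append((seg_start, i))
            seg_start = i
    segments.append((seg_start, len(sub_blocks)))
    out = []
    for a, b in segments:
        sub = _FakeAlignment(sub_blocks[a:b], qry_blocks[a:b], alignment.score)
        out.append(_block_stats(subject, query, sub))
    if len(out) > 1:
        # per-segment scores: recompute from match/mismatch/gap tallies is
        # aligner-specific; approximate by apportioning to matches
        total_m = sum(s.matches for s in out) or 1
        out = [
            AlignmentStats(
                s.subject_start, s.subject_end, s.query_start, s.query_end,
                s.matches, s.mismatches, s.columns, s.gap_openings,
                alignment.score * s.matches / total_m,
            )
            for s in out
        ]
    return out


class _FakeAlignment:
    def __init__(self, sub_blocks, qry_blocks, score):
        self.aligned = (sub_blocks, qry_blocks)
        self.score = score


def local_align_split(
    subject: str,
    query: str,
    aligner: Align.PairwiseAligner | None = None,
    max_internal_gap: int = 30,
) -> list[AlignmentStats]:
    """Best local alignment, reported as gap-split segments."""
    if aligner is None:
        aligner = make_local_aligner()
    if not subject or not query:
        return []
    alignments = aligner.align(subject, query)
    try:
        best = alignments[0]
    except IndexError:
        return []
    return [s for s in split_blocks_stats(subject, query, best, max_internal_gap) if s.columns > 0]


def local_align(subject: str, query: str, aligner: Align.PairwiseAligner | None = None) -> AlignmentStats | None:
    """Best local alignment of ``query`` against ``subject``; None if empty."""
    if aligner is None:
        aligner = make_local_aligner()
    if not subject or not query:
        return None
    alignments = aligner.align(subject, query)
    try:
        best = alignments[0]
    except IndexError:
        return None
    stats = _block_stats(subject, query, best)
    if stats.columns == 0:
        return None
    return stats


def global_align_stats(subject: str, query: str, aligner: Align.PairwiseAligner | None = None) -> AlignmentStats | None:
    """Free-end-gap global alignment; statistics cover the aligned core only.

    End-gap columns (the unaligned overhangs) are excluded; internal gap
    columns are included, matching the clustering identity definition
    (matches / alignment columns including internal gaps).
    """
    if aligner is None:
        aligner = make_global_aligner()
    if not subject or not query:
        return None
    alignments = aligner.align(subject, query)
    try:
        best = alignments[0]
    except IndexError:
        return None
    stats = _block_stats(subject, query, best)
    if stats.columns == 0:
        return None
    return stats


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fractional identity (0..1) of a free-end-gap global alignment."""
    stats = global_align_stats(a, b, aligner)
    if stats is None:
        return 0.0
    return stats.matches / stats.columns if stats.columns else 0.0
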