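"""Structural classification of CR1 candidate copies.

A CR1 copy is classified on an evidence ladder:

    fragment < anchored < full_length < intact

* ``anchored`` — the copy retains the distinctive 3' structure: an inverted
  repeat (hairpin) followed by a terminal microsatellite array.  Because
  LINE insertion truncates copies from the 5' end, even heavily truncated
  copies keep this tail, which makes it the universal detection handle.
* ``full_length`` — anchored, plus evidence of both the endonuclease (EN)
  and reverse transcriptase (RT) protein domains, with EN 5' of RT
  (the canonical CR1 domain order).
* ``intact`` — full-length, and both domain hits fall within a single
  open reading frame, i.e. the copy is potentially retrotransposition
  competent.

Domain evidence is pluggable: an external domain-hit table is authoritative
when provided; otherwise bundled canonical-style EN/RT marker peptides are
matched by translated alignment in all six frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .dna import IUPAC, motif_mismatches, revcomp
from .io_formats import Interval
from .pairwise import local_align, make_protein_aligner

__all__ = [
    "MicrosatMotif",
    "DomainHit",
    "read_domain_hits",
    "CR1Copy",
    "STATUS_ORDER",
    "BUILTIN_MOTIFS",
    "EN_MARKER_AA",
    "RT_MARKER_AA",
    "detect_microsatellite",
    "detect_hairpin",
    "find_orfs",
    "match_builtin_domains",
    "classify_copy",
    "analyze_sequence",
]

STATUS_ORDER = ("fragment", "anchored", "full_length", "intact")


@dataclass(frozen=True)
class MicrosatMotif:
    """A degenerate tandem-repeat motif anchoring the CR1 3' terminus."""

    motif: str
    min_copies: int = 2

    def __post_init__(self) -> None:
        bad = set(self.motif) - set(IUPAC)
        if bad:
            raise ValueError(f"motif contains non-IUPAC codes: {sorted(bad)}")


#: The standard avian CR1 octamer and the extended CR1-W 10-mer.
BUILTIN_MOTIFS: tuple[MicrosatMotif, ...] = (
    MicrosatMotif("ATTCTRTG"),
    MicrosatMotif("AAATTCYGTG"),
)


@dataclass(frozen=True)
class DomainHit:
    domain: str  # "EN" or "RT"
    start: int  # nucleotide offset on the copy sequence
    end: int
    frame: int  # 1..3 forward, -1..-3 reverse
    source: str = "builtin_marker"  # or "external_table"

    def __post_init__(self) -> None:
        if self.domain not in ("EN", "RT"):
            raise ValueError(f"domain must be EN or RT, got {self.domain!r}")


@dataclass
class CR1Copy:
    """A located repeat copy with structural anatomy flags and family label."""

    copy_id: str
    locus: Interval | None
    sequence: str  # sense strand of the element
    family_id: str = "unassigned"
    anchored_3prime: bool = False
    orfs: list[tuple[int, int, int]] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    status: str = "fragment"


# ---------------------------------------------------------------------------
# microsatellite


def detect_microsatellite(
    seq: str,
    motifs: tuple[MicrosatMotif, ...] = BUILTIN_MOTIFS,
    search_window_bp: int = 100,
) -> tuple[MicrosatMotif, tuple[int, int]] | None:
    """Find the 3'-terminal microsatellite array.

    An array is >= ``min_copies`` tandem copies of the motif where the first
    copy is IUPAC-consistent (0 mismatches) and each later copy may carry at
    most one mismatch.  Only arrays ending within ``search_window_bp`` of the
    3' terminus count.  The array ending nearest the 3' end wins; ties go to
    the longer array.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    window_start = max(0, n - search_window_bp)
    best: tuple[int, int, int, tuple[MicrosatMotif, tuple[int, int]]] | None = None
    for motif in motifs:
        m = len(motif.motif)
        for start in range(max(0, window_start - m * 8), n - m + 1):
            if motif_mismatches(seq[start : start + m], motif.motif) != 0:
                continue
            copies = 1
            end = start + m
            while end + m <= n and motif_mismatches(seq[end : end + m], motif.motif) <= 1:
                copies += 1
                end += m
            if copies < motif.min_copies or end < window_start:
                continue
            # rank: nearest 3' terminus first, then longer array
            key = (-(end), end - start, -start)
            if best is None or key > best[:3]:
                best = (*key, (motif, (start, end)))
    return None if best is None else best[3]


# ---------------------------------------------------------------------------
# hairpin


def detect_hairpin(
    seq: str,
    upstream_of: tuple[int, int],
    min_stem: int = 5,
    max_stem: int = 15,
    min_loop: int = 3,
    max_loop: int = 20,
    max_stem_mismatches: int = 1,
    hairpin_window: int = 60,
) -> tuple[int, int] | None:
    """Best inverted repeat whose 3' arm ends within ``hairpin_window`` bp
    upstream of the microsatellite.

    Best = longest stem; ties broken by smallest loop, then by proximity to
    the microsatellite.  A window that extends past the sequence start is
    clamped, not an error.
    """
    ms_start = upstream_of[0]
    lo = max(0, ms_start - hairpin_window)
    for stem in range(max_stem, min_stem - 1, -1):
        for loop in range(min_loop, max_loop + 1):
            # iterate 3' arm end positions, nearest the microsatellite first
            for end3 in range(ms_start, lo - 1, -1):
                left_start = end3 - stem - loop - stem
                if left_start < 0:
                    continue
                # right arm must equal revcomp(left arm) within mismatches
                mism = 0
                ok = True
                right = seq[end3 - stem : end3]
                # revcomp(left arm) == comp[n-left_end : n-left_start][::-1] — do direct compare
                left_rc = revcomp(seq[left_start : left_start + stem])
                for a, b in zip(right, left_rc):
                    if a != b:
                        mism += 1
                        if mism > max_stem_mismatches:
                            ok = False
                            break
                if ok:
                    return (left_start, end3)
    return None


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: str, min_codons: int = 600) -> list[tuple[int, int, int]]:
    """All forward-frame ORFs (ATG -> stop, standard code) with >= min_codons.

    Returned as (start, end, frame) with ``end`` including the stop codon;
    the codon count excludes the stop.  Sorted by start.
    """
    out: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        orf_start: int | None = None
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = pos
            elif codon in _STOPS:
                codons = (pos - orf_start) // 3
                if codons >= min_codons:
                    out.append((orf_start, pos + 3, frame + 1))
                orf_start = None
            pos += 3
    return sorted(out)


# ---------------------------------------------------------------------------
# domain markers

# Bundled canonical-style marker peptides (synthetic stand-ins written in the
# style of LINE APE endonuclease and reverse transcriptase cores; the RT
# marker carries the classic QGSVLSPLLF / YADD motifs).  They double as the
# domains embedded in simulated consensus sequences.
EN_MARKER_AA = "MKILSWNVRGLNSPIKRKRILAHLKKLKADIVFLQETHLTE"
RT_MARKER_AA = "LKGIPQGSVLSPLLFNIYMHDLDKGIESSIRLLQYADDTVLF"

_MARKERS = {"EN": EN_MARKER_AA, "RT": RT_MARKER_AA}


def match_builtin_domains(
    seq: str,
    min_identity: float = 60.0,
    min_coverage: float = 0.80,
) -> list[DomainHit]:
    """Translated-alignment search for the bundled EN/RT marker peptides.

    All six frames are scanned; a marker hits when a local protein alignment
    reaches >= ``min_identity`` percent identity over >= ``min_coverage`` of
    the marker length.  Hit coordinates are reported on the input sequence
    (forward axis) regardless of the matching frame.
    """
    aligner = make_protein_aligner()
    hits: list[DomainHit] = []
    n = len(seq)
    frames: list[tuple[int, str]] = []

    def _translate(s: str) -> str:
        trimmed = s[: len(s) - len(s) % 3]
        return str(Seq(trimmed).translate())

    for off in range(3):
        frames.append((off + 1, _translate(seq[off:])))
    rc = revcomp(seq)
    for off in range(3):
        frames.append((-(off + 1), _translate(rc[off:])))
    for domain, marker in _MARKERS.items():
        best: DomainHit | None = None
        best_score = 0.0
        for frame, prot in frames:
            if len(prot) < 5:
                continue
            stats = local_align(prot, marker, aligner)
            if stats is None:
                continue
            coverage = (stats.query_end - stats.query_start) / len(marker)
            if stats.identity < min_identity or coverage < min_coverage:
                continue
            if stats.score <= best_score:
                continue
            off = abs(frame) - 1
            aa_start, aa_end = stats.subject_start, stats.subject_end
            if frame > 0:
                nt_start = off + 3 * aa_start
                nt_end = off + 3 * aa_end
            else:
                # coordinates on the reverse-complement axis, mapped back
                nt_end = n - (off + 3 * aa_start)
                nt_start = n - (off + 3 * aa_end)
            best = DomainHit(domain=domain, start=nt_start, end=nt_end, frame=frame)
            best_score = stats.score
        if best is not None:
            hits.append(best)
    return sorted(hits, key=lambda h: h.start)


def read_domain_hits(path) -> dict[str, list[DomainHit]]:
    """Read an external domain-hit TSV: copy_id, domain, start, end, frame, source.

    External hits are authoritative over builtin marker matching when
    passed to :func:`analyze_sequence`.
    """
    out: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["copy_id", "domain", "start", "end", "frame", "source"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            copy_id, domain, start, end, frame, source = line.split("\t")
            try:
                hit = DomainHit(
                    domain=domain, start=int(start), end=int(end),
                    frame=int(frame), source=source,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.setdefault(copy_id, []).append(hit)
    return out


# ---------------------------------------------------------------------------
# classification


def classify_copy(copy: CR1Copy) -> str:
    """Assign the evidence-ladder status; monotone in evidence."""
    status = "fragment"
    if copy.anchored_3prime:
        status = "anchored"
        en = [h for h in copy.domain_hits if h.domain == "EN"]
        rt = [h for h in copy.domain_hits if h.domain == "RT"]
        if en and rt:
            en_hit = min(en, key=lambda h: h.start)
            rt_hit = min(rt, key=lambda h: h.start)
            if en_hit.start < rt_hit.start:  # canonical EN–RT order
                status = "full_length"
                for (ostart, oend, _frame) in copy.orfs:
                    if (
                        ostart <= en_hit.start
                        and en_hit.end <= oend
                        and ostart <= rt_hit.start
                        and rt_hit.end <= oend
                    ):
                        status = "intact"
                        break
    copy.status = status
    return status


def analyze_sequence(
    copy_id: str,
    seq: str,
    locus: Interval | None = None,
    motifs: tuple[MicrosatMotif, ...] = BUILTIN_MOTIFS,
    domain_hits: list[DomainHit] | None = None,
    min_orf_codons: int = 600,
    hairpin_params: dict | None = None,
) -> CR1Copy:
    """Run the full anatomy battery on a sense-strand sequence and classify.

    ``domain_hits`` from an external table take precedence over builtin
    marker matching when provided.
    """
    copy = CR1Copy(copy_id=copy_id, locus=locus, sequence=seq)
    ms = detect_microsatellite(seq, motifs=motifs)
    if ms is not None:
        _, ms_interval = ms
        hp = detect_hairpin(seq, upstream_of=ms_interval, **(hairpin_params or {}))
        copy.anchored_3prime = hp is not None
    if copy.anchored_3prime:
        copy.orfs = find_orfs(seq, min_codons=min_orf_codons)
        copy.domain_hits = (
            list(domain_hits) if domain_hits is not None else match_builtin_domains(seq)
        )
    classify_copy(copy)
    return copy
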