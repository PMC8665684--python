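"""Small nucleotide utilities: complement, IUPAC degeneracy, k-mer encoding."""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degenerate code -> set of concrete bases
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

VALID_NUCLEOTIDES = frozenset(IUPAC)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def iupac_base_match(base: str, code: str) -> bool:
    """True if concrete ``base`` is consistent with degenerate ``code``."""
    allowed = IUPAC.get(code)
    if allowed is None:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}")
    return base in allowed


def motif_mismatches(window: str, motif: str) -> int:
    """Number of positions of ``window`` inconsistent with degenerate ``motif``."""
    if len(window) != len(motif):
        raise ValueError("window and motif lengths differ")
    return sum(0 if b in IUPAC[m] else 1 for b, m in zip(window, motif))


_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other character becomes -1."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE_TABLE[raw].astype(np.int64)


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; windows containing non-ACGT get -1."""
    b = encode_bases(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = b[j : j + n]
        codes = codes * 4 + np.where(col < 0, 0, col)
        bad |= col < 0
    codes[bad] = -1
    return codes


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
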