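"""Independent reference implementations used to verify the package.

These deliberately share no code with cr1kit's own alignment/search paths:
full-matrix affine-gap Smith–Waterman and Needleman–Wunsch in numpy, and
an exhaustive inverted-repeat scan.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def smith_waterman(
    subject: str,
    query: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
):
    """Full-DP affine-gap local alignment.

    Returns (subject_start, subject_end, query_start, query_end,
    identity_percent, score) of the optimal local alignment, or None.
    Gap scoring matches cr1kit's convention: the first gap position costs
    ``gap_open``, each further position ``gap_extend``.
    """
    n, m = len(subject), len(query)
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (moving along subject)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in subject (moving along query)
    for i in range(1, n + 1):
        sub_scores = np.where(q == s[i - 1], match, mismatch)
        Ix[i] = np.maximum(H[i - 1] + gap_open, Ix[i - 1] + gap_extend)
        # Iy has a row-internal recurrence: do it serially
        prev_h = H[i]
        diag = H[i - 1, :-1] + sub_scores
        for j in range(1, m + 1):
            Iy[i, j] = max(H[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            H[i, j] = max(0.0, diag[j - 1], Ix[i, j], Iy[i, j])
    score = H.max()
    if score <= 0:
        return None
    i, j = np.unravel_index(np.argmax(H), H.shape)
    end_i, end_j = int(i), int(j)
    # traceback
    matches = 0
    columns = 0
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            sub = match if s[i - 1] == q[j - 1] else mismatch
            if np.isclose(H[i, j], H[i - 1, j - 1] + sub):
                matches += s[i - 1] == q[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif np.isclose(H[i, j], Ix[i, j]):
                state = "Ix"
            elif np.isclose(H[i, j], Iy[i, j]):
                state = "Iy"
            else:  # local start
                break
        elif state == "Ix":
            columns += 1
            if np.isclose(Ix[i, j], H[i - 1, j] + gap_open):
                state = "H"
            i -= 1
        else:  # Iy
            columns += 1
            if np.isclose(Iy[i, j], H[i, j - 1] + gap_open):
                state = "H"
            j -= 1
    identity = 100.0 * matches / columns if columns else 0.0
    return int(i), end_i, int(j), end_j, identity, float(score)


def global_identity_free_ends(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Linear-gap free-end-gap global alignment identity (0..1).

    Identity = matches / aligned columns (internal gaps included, terminal
    overhangs excluded).  Used as a cross-check of the clustering identity;
    linear gap costs keep it independent of the package's affine scheme, so
    comparisons should allow a small tolerance.
    """
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1))
    # free leading end gaps: first row/col stay 0
    for i in range(1, n + 1):
        S[i, 1:] = 0  # placeholder; filled below
    best = None
    M = np.zeros((n + 1, m + 1))  # matches along optimal path
    C = np.zeros((n + 1, m + 1))  # columns along optimal path
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            options = (
                (S[i - 1, j - 1] + sub, M[i - 1, j - 1] + (a[i - 1] == b[j - 1]), C[i - 1, j - 1] + 1),
                (S[i - 1, j] + gap, M[i - 1, j], C[i - 1, j] + 1),
                (S[i, j - 1] + gap, M[i, j - 1], C[i, j - 1] + 1),
            )
            S[i, j], M[i, j], C[i, j] = max(options)
    # free trailing end gaps: best over last row/column
    cand = [(S[n, j], M[n, j], C[n, j]) for j in range(m + 1)]
    cand += [(S[i, m], M[i, m], C[i, m]) for i in range(n + 1)]
    _, mm, cc = max(cand)
    return mm / cc if cc else 0.0


def exhaustive_inverted_repeats(
    seq: str,
    min_stem: int = 5,
    max_stem: int = 15,
    min_loop: int = 3,
    max_loop: int = 20,
    max_mismatches: int = 1,
) -> list[tuple[int, int, int, int]]:
    """All inverted repeats as (left_start, stem, loop, mismatches), O(n^2)-ish."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    n = len(seq)
    for stem in range(min_stem, max_stem + 1):
        for loop in range(min_loop, max_loop + 1):
            span = 2 * stem + loop
            for start in range(0, n - span + 1):
                left = seq[start : start + stem]
                right = seq[start + stem + loop : start + span]
                mism = sum(
                    1
                    for x, y in zip(left, reversed(right))
                    if comp.get(x) != y
                )
                if mism <= max_mismatches:
                    out.append((start, stem, loop, mism))
    return out


def dollo_consistent_branches(tree, states: dict[str, str]) -> set[str]:
    """Brute-force: every branch whose single gain explains the vector.

    A branch is consistent when all present leaves descend from it, no
    absent leaf descends from it, and unscorable leaves are unconstrained.
    """
    present = {s for s, c in states.items() if c == "present"}
    absent = {s for s, c in states.items() if c == "absent"}
    out = set()
    for branch in tree.branch_ids:
        clade = tree.clade_of(branch)
        if present <= clade and not (absent & clade):
            out.add(branch)
    return out
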