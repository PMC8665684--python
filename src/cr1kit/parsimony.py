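"""Dollo-parsimony placement of insertions on the species tree.

A retrotransposon insertion arises once and is never regained, and the
scoring deliberately has no excision category, so a presence/absence
vector is reconciled under Dollo parsimony: the gain branch must subtend
every species scored present and no species scored absent.  Unscorable
species constrain nothing.  When several branches qualify (unscorables
widen the interval) the most recent candidate is reported as the point
assignment and the full candidate set is kept as ``ambiguous_range``; a
vector with an absent species inside the present clade is surfaced as
``conflicted`` rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import SpeciesTree

__all__ = [
    "PresenceVector",
    "BranchAssignment",
    "ExpansionSummary",
    "SUPPORT_LEVELS",
    "assign_branch",
    "summarize",
]

SUPPORT_LEVELS = ("unambiguous", "ambiguous_range", "conflicted")


@dataclass(frozen=True)
class PresenceVector:
    insertion_id: str
    family_id: str
    focal_species: str
    calls: dict[str, str]  # species -> present | absent | unscorable

    def __post_init__(self) -> None:
        if self.calls.get(self.focal_species) != "present":
            raise ValueError(
                f"{self.insertion_id}: focal species {self.focal_species!r} "
                f"must be scored present"
            )
        bad = {v for v in self.calls.values()} - {"present", "absent", "unscorable"}
        if bad:
            raise ValueError(f"unknown call states: {sorted(bad)}")


@dataclass(frozen=True)
class BranchAssignment:
    insertion_id: str
    family_id: str
    branch: str  # branch id, or "conflicted"
    support: str
    ambiguous_range: tuple[str, ...] = ()


@dataclass
class ExpansionSummary:
    per_branch_family: pd.DataFrame  # branch, family_id, count, reportable
    conflicted: int
    ambiguous: int
    total: int


def assign_branch(vector: PresenceVector, tree: SpeciesTree) -> BranchAssignment:
    """Most parsimonious (Dollo) gain branch for one presence vector.

    Candidates are the branches from the MRCA of the present species up
    toward the root, stopping as soon as an absent species would be
    included.  The most recent candidate is the point assignment; all
    candidates form the ambiguous range.
    """
    unknown = set(vector.calls) - set(tree.leaves)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    present = {s for s, c in vector.calls.items() if c == "present"}
    absent = {s for s, c in vector.calls.items() if c == "absent"}
    try:
        mrca = tree.mrca_branch(present)
    except ValueError:
        # present on both sides of the root: the gain predates the sampled
        # tree; report the pseudo-branch "root" and flag it.
        if absent:
            return BranchAssignment(
                insertion_id=vector.insertion_id,
                family_id=vector.family_id,
                branch="conflicted",
                support="conflicted",
            )
        return BranchAssignment(
            insertion_id=vector.insertion_id,
            family_id=vector.family_id,
            branch="root",
            support="ambiguous_range",
            ambiguous_range=("root",),
        )
    if absent & tree.clade_of(mrca):
        return BranchAssignment(
            insertion_id=vector.insertion_id,
            family_id=vector.family_id,
            branch="conflicted",
            support="conflicted",
        )
    candidates = [mrca]
    node = mrca
    while True:
        parent = tree.parent_branch(node)
        if parent is None:
            break
        if absent & tree.clade_of(parent):
            break
        candidates.append(parent)
        node = parent
    support = "unambiguous" if len(candidates) == 1 else "ambiguous_range"
    return BranchAssignment(
        insertion_id=vector.insertion_id,
        family_id=vector.family_id,
        branch=candidates[0],  # most recent candidate
        support=support,
        ambiguous_range=tuple(candidates),
    )


def summarize(
    assignments: list[BranchAssignment],
    tree: SpeciesTree,
    min_count: int = 10,
) -> ExpansionSummary:
    """Per-(branch, family) insertion counts.

    Conflicted assignments are tallied separately, never into branch
    counts.  ``reportable`` flags families with strictly more than
    ``min_count`` assignments on a branch — a display filter only; the
    stored counts are complete.
    """
    if not assignments:
        raise ValueError("no assignments to summarise")
    counts: dict[tuple[str, str], int] = {}
    conflicted = 0
    ambiguous = 0
    for a in assignments:
        if a.branch == "conflicted":
            conflicted += 1
            continue
        if a.branch != "root" and a.branch not in tree.branch_ids:
            raise KeyError(f"assignment to unknown branch {a.branch!r}")
        if a.support == "ambiguous_range":
            ambiguous += 1
        key = (a.branch, a.family_id)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "branch": b,
            "family_id": fam,
            "count": n,
            "reportable": n > min_count,
        }
        for (b, fam), n in sorted(counts.items())
    ]
    frame = pd.DataFrame(rows, columns=["branch", "family_id", "count", "reportable"])
    return ExpansionSummary(
        per_branch_family=frame,
        conflicted=conflicted,
        ambiguous=ambiguous,
        total=len(assignments),
    )
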