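"""End-to-end orchestration: discover -> classify -> cluster -> landscape
-> date-loci -> reconcile, driven by a single validated config.

Every output table is stamped with the config hash and seed; a rerun with
the same config is bit-identical for the deterministic stages (all of
them — the pipeline is single-process and all tables use stable sort
keys).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import anatomy, divergence, homology, parsimony, presence_absence
from .dna import revcomp
from .io_formats import (
    GenomeAssembly,
    read_fasta,
    read_species_tree,
    write_insertion_table,
)

log = logging.getLogger("cr1kit")

__all__ = [
    "PipelineConfig",
    "QualityStratification",
    "run_pipeline",
    "stratify_by_n50",
    "discover_copies",
]

_KNOWN_KEYS = {
    "assemblies",
    "tree",
    "library",
    "output_dir",
    "rng_seed",
    "orders",
    "search",
    "cascade",
    "cluster_identity",
    "min_element_bp",
    "min_orf_codons",
    "target_species",
}


@dataclass
class PipelineConfig:
    assemblies: dict[str, str]  # species_id -> FASTA path
    tree: str  # newick path
    library: str  # FASTA path of the starting CR1 reference library
    output_dir: str
    rng_seed: int = 0
    orders: dict[str, str] = field(default_factory=dict)  # species -> order label
    search: dict = field(default_factory=dict)
    cascade: dict = field(default_factory=dict)
    cluster_identity: float = 0.9
    min_element_bp: int = 2700
    min_orf_codons: int = 600
    target_species: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for sp, path in self.assemblies.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"assembly for {sp!r} not found: {path}")
        for label, path in (("tree", self.tree), ("library", self.library)):
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} file not found: {path}")

    def config_hash(self) -> str:
        """Hash of every scientific parameter (the output location is not one)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class QualityStratification:
    table: pd.DataFrame  # species_id, scaffold_n50, quartile, full_length, intact
    degenerate: bool  # all N50s equal -> single stratum


# ---------------------------------------------------------------------------
# discovery


def discover_copies(
    library: homology.RepeatLibrary,
    assembly: GenomeAssembly,
    search_params: homology.SearchParams | None = None,
    min_fragment_bp: int = 100,
    min_orf_codons: int = 600,
    hits: list | None = None,
) -> list[anatomy.CR1Copy]:
    """Homology discovery + anatomy classification of CR1 copies.

    Hits of all library entries are chained (50 bp tolerance), merged
    across queries by locus, extracted on the element sense strand and
    pushed through the anatomy battery.  ``hits`` bypasses the internal
    search with externally supplied alignments (e.g. from a 12-column
    tabular file).
    """
    params = search_params or homology.SearchParams()
    if hits is None:
        hits = homology.search(library, assembly, params)
    chained = homology.chain_hits(hits)
    # merge loci found by different queries: keep the longest hit per region
    chained.sort(key=lambda h: (-h.subject_interval.length, h.query_id))
    kept = []
    for h in chained:
        if h.subject_interval.length < min_fragment_bp:
            continue
        if any(
            k.subject_interval.scaffold_id == h.subject_interval.scaffold_id
            and k.subject_interval.overlap(h.subject_interval)
            >= 0.5 * h.subject_interval.length
            for k in kept
        ):
            continue
        kept.append(h)
    copies = []
    for i, h in enumerate(
        sorted(kept, key=lambda h: (h.subject_interval.scaffold_id, h.subject_interval.start))
    ):
        iv = h.subject_interval
        seq = assembly.fetch(iv)
        if iv.strand == "-":
            seq = revcomp(seq)
        copy = anatomy.analyze_sequence(
            f"{assembly.species_id}.copy{i:05d}", seq, locus=iv, min_orf_codons=min_orf_codons
        )
        copies.append(copy)
    return copies


# ---------------------------------------------------------------------------
# N50 stratification


def stratify_by_n50(per_species_counts: pd.DataFrame) -> QualityStratification:
    """Quartile stratification of assemblies by scaffold N50.

    Expects columns species_id, scaffold_n50, full_length, intact.
    Quartile boundaries sit at the 25/50/75 percentiles within the set;
    with fewer than 4 species (or all-equal N50s) everything lands in a
    single flagged stratum.
    """
    df = per_species_counts.copy().sort_values("species_id").reset_index(drop=True)
    n50 = df["scaffold_n50"].to_numpy(dtype=float)
    if len(df) < 4 or len(set(n50)) == 1:
        df["quartile"] = 1
        return QualityStratification(table=df, degenerate=True)
    import numpy as np

    q25, q50, q75 = np.percentile(n50, [25, 50, 75])
    def quart(x: float) -> int:
        if x <= q25:
            return 1
        if x <= q50:
            return 2
        if x <= q75:
            return 3
        return 4
    df["quartile"] = [quart(x) for x in n50]
    return QualityStratification(table=df, degenerate=False)


# ---------------------------------------------------------------------------
# full pipeline


def _stamp(path: str, frame: pd.DataFrame, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg.config_hash()} seed={cfg.rng_seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages in order; returns the output directory.

    Any stage failure raises with the stage name and offending input id.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    search_params = homology.SearchParams(**config.search)
    cascade_params = presence_absence.CascadeParams(**config.cascade)
    tree = read_species_tree(config.tree)
    assemblies = {
        sp: read_fasta(path, species_id=sp) for sp, path in sorted(config.assemblies.items())
    }
    library = homology.RepeatLibrary(
        read_fasta(config.library, species_id="library").scaffolds,
        provenance="bundled_reference",
    )

    # discover + classify
    copies_by_species: dict[str, list[anatomy.CR1Copy]] = {}
    rows = []
    for sp in sorted(assemblies):
        try:
            copies = discover_copies(
                library, assemblies[sp], search_params, min_orf_codons=config.min_orf_codons
            )
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"stage discover failed for {sp!r}: {exc}") from exc
        copies_by_species[sp] = copies
        for c in copies:
            rows.append(
                {
                    "species_id": sp,
                    "copy_id": c.copy_id,
                    "scaffold_id": c.locus.scaffold_id,
                    "start": c.locus.start,
                    "end": c.locus.end,
                    "strand": c.locus.strand,
                    "status": c.status,
                    "family_id": c.family_id,
                }
            )
        log.info("discover[%s]: %d copies", sp, len(copies))
    copies_frame = pd.DataFrame(
        rows,
        columns=["species_id", "copy_id", "scaffold_id", "start", "end", "strand", "status", "family_id"],
    )

    # cluster full-length copies into a centroid library
    full_seqs = {
        c.copy_id: c.sequence
        for sp in sorted(copies_by_species)
        for c in copies_by_species[sp]
        if c.status in ("full_length", "intact")
    }
    if full_seqs:
        centroid_lib = homology.cluster_centroids(full_seqs, config.cluster_identity)
    else:
        centroid_lib = library
    family_lib = homology.RepeatLibrary(
        {**library.entries, **centroid_lib.entries}, provenance="centroid"
    )

    # family assignment + divergence landscape
    div_rows = []
    for sp in sorted(copies_by_species):
        records = []
        for c in copies_by_species[sp]:
            if not c.anchored_3prime:
                continue
            fam = homology.assign_family(c.sequence, family_lib, search_params)
            c.family_id = fam
            if fam == "unassigned":
                continue
            rec = divergence.copy_divergence(
                c.copy_id, c.sequence, family_lib.entries[fam],
                family_id=fam, representative_id=fam,
            )
            if rec.ok:
                records.append(rec)
        scape = divergence.build_landscape(records, species_id=sp)
        frame = scape.to_frame()
        frame.insert(0, "species_id", sp)
        div_rows.append(frame)
        assert scape.total == len(records)  # conservation check
    landscape_frame = (
        pd.concat(div_rows, ignore_index=True)
        if div_rows
        else pd.DataFrame(columns=["species_id", "family_id", "bin", "d_lo", "d_hi", "count"])
    )

    # presence/absence dating
    scorer = presence_absence.PresenceAbsenceScorer(assemblies, search_params, cascade_params)
    targets = config.target_species or sorted(assemblies)
    call_records = []
    vectors = []
    for sp in sorted(copies_by_species):
        anchored = [c for c in copies_by_species[sp] if c.anchored_3prime]
        queries, _excluded = presence_absence.select_candidates(
            anchored, assemblies[sp], cascade_params
        )
        for q in queries:
            calls = {}
            for tsp in targets:
                if tsp == sp:
                    continue
                call = scorer.score(q, tsp)
                call_records.append(call)
                calls[tsp] = {"shared": "present", "absent": "absent"}.get(
                    call.call, "unscorable"
                )
            calls[sp] = "present"
            vectors.append(
                parsimony.PresenceVector(
                    insertion_id=q.insertion_id,
                    family_id=q.family_id,
                    focal_species=sp,
                    calls=calls,
                )
            )
    n_pairs = sum(1 for _ in call_records)
    assert n_pairs == len(call_records)  # partition: every (query, target) has one call

    # reconcile
    assignments = [parsimony.assign_branch(v, tree) for v in vectors]
    summary = (
        parsimony.summarize(assignments, tree) if assignments else None
    )

    # N50 stratification report
    strat_rows = []
    for sp in sorted(assemblies):
        copies = copies_by_species[sp]
        strat_rows.append(
            {
                "species_id": sp,
                "scaffold_n50": assemblies[sp].scaffold_n50,
                "full_length": sum(c.status in ("full_length", "intact") for c in copies),
                "intact": sum(c.status == "intact" for c in copies),
            }
        )
    strat = stratify_by_n50(pd.DataFrame(strat_rows))

    # write outputs
    _stamp(os.path.join(out, "copies.tsv"), copies_frame, config)
    _stamp(os.path.join(out, "landscape.tsv"), landscape_frame, config)
    write_insertion_table(call_records, os.path.join(out, "locus_calls.tsv"))
    write_insertion_table(assignments, os.path.join(out, "branch_assignments.tsv"))
    if summary is not None:
        _stamp(os.path.join(out, "expansion_summary.tsv"), summary.per_branch_family, config)
    else:
        _stamp(
            os.path.join(out, "expansion_summary.tsv"),
            pd.DataFrame(columns=["branch", "family_id", "count", "reportable"]),
            config,
        )
    _stamp(os.path.join(out, "n50_stratification.tsv"), strat.table, config)
    with open(os.path.join(out, "library.fasta"), "w") as fh:
        for label, seq in family_lib.entries.items():
            fh.write(f">{label}\n{seq}\n")
    return out
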