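import numpy as np
import pytest

from cr1kit.anatomy import (
    BUILTIN_MOTIFS,
    CR1Copy,
    DomainHit,
    MicrosatMotif,
    analyze_sequence,
    classify_copy,
    detect_hairpin,
    detect_microsatellite,
    find_orfs,
    match_builtin_domains,
    EN_MARKER_AA,
    RT_MARKER_AA,
)
from cr1kit.dna import IUPAC, iupac_base_match, motif_mismatches, random_dna, revcomp
from cr1kit.simulate import make_cr1_consensus


OCTAMER = BUILTIN_MOTIFS[0]
TENMER = BUILTIN_MOTIFS[1]


class TestIupac:
    def test_one_substitution_neighbours_of_octamer(self):
        """The octamer matcher accepts exactly the IUPAC-consistent strings
        among all one-substitution neighbours of a concrete instance."""
        base = "ATTCTGTG"
        for i in range(8):
            for b in "ACGT":
                variant = base[:i] + b + base[i + 1 :]
                expected = all(
                    v in IUPAC[m] for v, m in zip(variant, OCTAMER.motif)
                )
                assert (motif_mismatches(variant, OCTAMER.motif) == 0) == expected

    def test_one_substitution_neighbours_of_tenmer(self):
        base = "AAATTCCGTG"
        for i in range(10):
            for b in "ACGT":
                variant = base[:i] + b + base[i + 1 :]
                expected = all(
                    v in IUPAC[m] for v, m in zip(variant, TENMER.motif)
                )
                assert (motif_mismatches(variant, TENMER.motif) == 0) == expected

    def test_degenerate_semantics_match_biopython_table(self):
        from Bio.Data.IUPACData import ambiguous_dna_values

        for code, bases in ambiguous_dna_values.items():
            if code == "X":
                continue
            for b in "ACGT":
                assert iupac_base_match(b, code) == (b in bases)


class TestMicrosatellite:
    def test_octamer_with_r_degeneracy(self):
        seq = "G" * 50 + "ATTCTGTGATTCTATG"
        motif, (start, end) = detect_microsatellite(seq)
        assert motif.motif == "ATTCTRTG"
        assert (start, end) == (50, 66)

    def test_tenmer_with_y_degeneracy(self):
        seq = "G" * 50 + "AAATTCCGTGAAATTCTGTG"
        motif, (start, end) = detect_microsatellite(seq)
        assert motif.motif == "AAATTCYGTG"
        assert (start, end) == (50, 70)

    def test_c_is_not_r(self):
        assert detect_microsatellite("G" * 50 + "ATTCTCTGATTCTCTG") is None

    def test_array_outside_window_ignored(self):
        seq = "ATTCTGTG" * 3 + "G" * 200
        assert detect_microsatellite(seq, search_window_bp=100) is None

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            detect_microsatellite("")

    def test_single_copy_not_an_array(self):
        assert detect_microsatellite("G" * 60 + "ATTCTGTG") is None


class TestHairpin:
    def test_constructed_perfect_inverted_repeat(self):
        stem, loop = "GGCGCGAA", "ATTTCG"
        seq = "T" * 40 + stem + loop + revcomp(stem) + "ATTCTGTGATTCTGTG"
        ms = detect_microsatellite(seq)
        assert ms is not None
        hp = detect_hairpin(seq, upstream_of=ms[1])
        assert hp is not None
        start, end = hp
        assert start <= 40 + len(stem)
        assert end == 40 + 2 * len(stem) + len(loop)

    def test_agrees_with_exhaustive_oracle(self):
        from oracles import exhaustive_inverted_repeats

        rng = np.random.default_rng(17)
        for _ in range(25):
            seq = random_dna(rng, 120)
            found = detect_hairpin(seq, upstream_of=(len(seq), len(seq)), hairpin_window=len(seq))
            oracle = exhaustive_inverted_repeats(seq)
            assert (found is not None) == bool(oracle)
            if found is not None:
                best_stem = max(s for (_, s, _, _) in oracle)
                # detector reports the longest stem the oracle can find
                left, right = found
                assert any(s == best_stem for (_, s, _, _) in oracle)

    def test_window_rule(self):
        stem, loop = "GGCGCGAA", "ATTTCG"
        hairpin = stem + loop + revcomp(stem)
        seq = "T" * 10 + hairpin + "T" * 100 + "ATTCTGTGATTCTGTG"
        ms = detect_microsatellite(seq)
        assert detect_hairpin(seq, upstream_of=ms[1], hairpin_window=60) is None
        assert detect_hairpin(seq, upstream_of=ms[1], hairpin_window=150) is not None

    def test_window_clamped_at_sequence_start(self):
        seq = "ATTCTGTGATTCTGTG"
        # microsatellite at position 0: window extends past the start; no error
        assert detect_hairpin(seq, upstream_of=(0, 16)) is None


class TestOrfs:
    @staticmethod
    def _coding(n_codons, rng):
        codons = ["GCT", "GAA", "TGG", "CAT", "ATT", "AAA"]
        return "".join(codons[i] for i in rng.integers(0, len(codons), n_codons))

    def test_exact_600_codons(self):
        rng = np.random.default_rng(0)
        seq = "ATG" + self._coding(599, rng) + "TAA"
        orfs = find_orfs(seq, min_codons=600)
        assert orfs == [(0, 1803, 1)]

    def test_internal_stop_splits_orf(self):
        rng = np.random.default_rng(0)
        seq = "ATG" + self._coding(299, rng) + "TAG" + self._coding(299, rng) + "TAA"
        assert find_orfs(seq, min_codons=600) == []

    def test_too_short_sequence(self):
        assert find_orfs("ATGAAATAA", min_codons=600) == []

    def test_all_frames_scanned(self):
        rng = np.random.default_rng(1)
        seq = "GG" + "ATG" + self._coding(599, rng) + "TAA"
        orfs = find_orfs(seq, min_codons=600)
        assert orfs == [(2, 1805, 3)]


class TestDomains:
    def test_markers_found_in_consensus(self, families):
        hits = match_builtin_domains(families[0].consensus)
        domains = {h.domain for h in hits}
        assert domains == {"EN", "RT"}
        en = next(h for h in hits if h.domain == "EN")
        rt = next(h for h in hits if h.domain == "RT")
        assert en.start < rt.start
        assert all(h.frame == 1 for h in hits)

    def test_reverse_complement_orientation_normalised(self, families):
        hits = match_builtin_domains(revcomp(families[0].consensus))
        assert {h.domain for h in hits} == {"EN", "RT"}
        assert all(h.frame < 0 for h in hits)
        n = len(families[0].consensus)
        for h in hits:
            assert 0 <= h.start < h.end <= n

    def test_scrambled_marker_not_found(self):
        """A marker with half its residues shuffled falls below the identity
        floor (verified against a direct alignment of the peptides)."""
        from cr1kit.pairwise import local_align, make_protein_aligner
        from cr1kit.simulate import _encode_peptide

        rng = np.random.default_rng(3)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        aa = list(EN_MARKER_AA)
        idx = rng.choice(len(aa), size=len(aa) // 2, replace=False)
        for i in idx:
            aa[i] = residues[(residues.index(aa[i]) + 1 + int(rng.integers(0, 19))) % 20]
        scrambled = "".join(aa)
        stats = local_align(scrambled, EN_MARKER_AA, make_protein_aligner())
        # direct-alignment identity over >=80% of the marker is below 60%
        if stats is not None and (stats.query_end - stats.query_start) >= 0.8 * len(EN_MARKER_AA):
            assert stats.identity < 60.0
        seq = _encode_peptide(scrambled) + "T" * 200
        assert all(h.domain != "EN" for h in match_builtin_domains(seq))


class TestExternalDomainTable:
    def test_roundtrip_and_precedence(self, tmp_path, families):
        from cr1kit.anatomy import read_domain_hits

        p = tmp_path / "domains.tsv"
        p.write_text(
            "copy_id\tdomain\tstart\tend\tframe\tsource\n"
            "c1\tEN\t0\t123\t1\texternal_table\n"
            "c1\tRT\t1272\t1398\t1\texternal_table\n"
        )
        hits = read_domain_hits(p)
        assert {h.domain for h in hits["c1"]} == {"EN", "RT"}
        # external hits are authoritative for classification
        copy = analyze_sequence("c1", families[0].consensus, domain_hits=hits["c1"])
        assert copy.status == "intact"
        assert all(h.source == "external_table" for h in copy.domain_hits)

    def test_bad_domain_rejected(self, tmp_path):
        from cr1kit.anatomy import read_domain_hits

        p = tmp_path / "domains.tsv"
        p.write_text(
            "copy_id\tdomain\tstart\tend\tframe\tsource\n"
            "c1\tXX\t0\t10\t1\texternal_table\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_domain_hits(p)


class TestClassification:
    def test_intact_when_domains_share_an_orf(self, families):
        copy = analyze_sequence("c", families[0].consensus)
        assert copy.status == "intact"

    def test_stop_between_domains_downgrades_to_full_length(self, families):
        cons = families[0].consensus
        hits = match_builtin_domains(cons)
        en = next(h for h in hits if h.domain == "EN")
        rt = next(h for h in hits if h.domain == "RT")
        mid = (en.end + rt.start) // 2
        mid -= mid % 3  # keep the reading frame, just insert a stop codon
        broken = cons[:mid] + "TAA" + cons[mid + 3 :]
        copy = analyze_sequence("c", broken)
        assert copy.status == "full_length"

    def test_single_domain_stays_anchored(self, families):
        copy = analyze_sequence("c", families[0].consensus)
        rt_only = [h for h in copy.domain_hits if h.domain == "RT"]
        demoted = CR1Copy(
            copy_id="c",
            locus=None,
            sequence=copy.sequence,
            anchored_3prime=True,
            orfs=copy.orfs,
            domain_hits=rt_only,
        )
        assert classify_copy(demoted) == "anchored"

    def test_monotone_in_evidence(self, families):
        """Adding a domain hit or anchoring never lowers the status."""
        copy = analyze_sequence("c", families[0].consensus)
        order = {"fragment": 0, "anchored": 1, "full_length": 2, "intact": 3}
        for subset in ([], copy.domain_hits[:1], copy.domain_hits):
            weaker = CR1Copy(
                copy_id="c", locus=None, sequence=copy.sequence,
                anchored_3prime=True, orfs=copy.orfs, domain_hits=list(subset),
            )
            weaker_status = classify_copy(weaker)
            assert order[weaker_status] <= order[copy.status]
        unanchored = CR1Copy(
            copy_id="c", locus=None, sequence=copy.sequence,
            anchored_3prime=False, orfs=copy.orfs, domain_hits=copy.domain_hits,
        )
        assert classify_copy(unanchored) == "fragment"

    def test_en_must_precede_rt(self, families):
        copy = analyze_sequence("c", families[0].consensus)
        en = next(h for h in copy.domain_hits if h.domain == "EN")
        rt = next(h for h in copy.domain_hits if h.domain == "RT")
        swapped = [
            DomainHit("EN", rt.start, rt.end, rt.frame),
            DomainHit("RT", en.start, en.end, en.frame),
        ]
        inverted = CR1Copy(
            copy_id="c", locus=None, sequence=copy.sequence,
            anchored_3prime=True, orfs=copy.orfs, domain_hits=swapped,
        )
        assert classify_copy(inverted) == "anchored"


class TestOnSimulatorOutput:
    def test_unmutated_copies_classify_by_truth_anatomy(self, clean_sim):
        """Substitution-free simulator output: every full-length copy is
        intact; every truncated copy is anchored and never full-length."""
        _, assemblies, truths = clean_sim
        checked = 0
        for truth in truths:
            present = [sp for sp, iv in truth.loci.items() if iv is not None]
            sp = present[0]
            seq = assemblies[sp].fetch(truth.loci[sp])
            if truth.strand == "-":
                seq = revcomp(seq)
            copy = analyze_sequence(truth.insertion_id, seq)
            if truth.anatomy == "full_length":
                assert copy.status == "intact"
            else:
                assert copy.status == "anchored"
            checked += 1
        assert checked > 0
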