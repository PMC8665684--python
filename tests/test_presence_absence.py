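import numpy as np
import pytest

from cr1kit.anatomy import CR1Copy
from cr1kit.dna import random_dna, revcomp
from cr1kit.io_formats import GenomeAssembly, Interval
from cr1kit.presence_absence import (
    CALLS,
    CascadeParams,
    score_locus,
    select_candidates,
    sweep_boundary_param,
)


def _copy(iv):
    return CR1Copy(copy_id="c", locus=iv, sequence="")


class TestSelectCandidates:
    """Bit-exact behaviour of each published candidate filter."""

    @pytest.fixture()
    def assembly(self):
        rng = np.random.default_rng(0)
        return GenomeAssembly("sp", {"s": random_dna(rng, 5_000)})

    def test_size_window(self, assembly):
        for length, kept in [(99, False), (100, True), (600, True), (601, False), (650, False)]:
            queries, excluded = select_candidates(
                [_copy(Interval("s", 2000, 2000 + length))], assembly
            )
            assert bool(queries) == kept, f"length {length}"
            if not kept:
                assert "size window" in excluded[0][1]

    def test_contig_edge_rule(self, assembly):
        # 300 bp copy starting 400 bp from the scaffold start: too close
        queries, excluded = select_candidates([_copy(Interval("s", 400, 700))], assembly)
        assert queries == [] and "edge" in excluded[0][1]
        # exactly 600 bp from both ends is allowed
        queries, _ = select_candidates([_copy(Interval("s", 600, 900))], assembly)
        assert len(queries) == 1

    def test_flank_n_fraction_boundary(self):
        """150/600 N (25.0%) kept; 151/600 (25.2%) dropped — strictly more
        than 25% discards."""
        rng = np.random.default_rng(1)
        bg = random_dna(rng, 5_000)
        for n_count, kept in [(150, True), (151, False)]:
            seq = bg[:1000] + "N" * n_count + bg[1000 + n_count :]
            asm = GenomeAssembly("sp", {"s": seq})
            # copy starts at 1600: its 5' flank is [1000, 1600) holding the Ns
            queries, excluded = select_candidates([_copy(Interval("s", 1600, 1900))], asm)
            assert bool(queries) == kept, f"{n_count} Ns"
            if not kept:
                assert "N fraction" in excluded[0][1]

    def test_query_layout(self, assembly):
        (q,) = select_candidates([_copy(Interval("s", 2000, 2300))], assembly)[0]
        assert len(q.flank5) == len(q.flank3) == 600
        assert q.query_seq == q.flank5 + assembly.scaffolds["s"][2000:2300] + q.flank3
        assert q.cr1_length == 300


class TestCascade:
    """Constructed focal/target genome pairs exercising each cascade exit."""

    @pytest.fixture()
    def locus(self):
        rng = np.random.default_rng(7)
        left = random_dna(rng, 2_000)
        right = random_dna(rng, 2_000)
        cr1 = random_dna(rng, 300)
        focal = GenomeAssembly("focal", {"s": left + cr1 + right})
        (query,) = select_candidates([_copy(Interval("s", 2000, 2300))], focal)[0]
        return left, cr1, right, query

    def test_full_span_shared(self, locus):
        left, cr1, right, query = locus
        target = GenomeAssembly("t", {"x": left + cr1 + right})
        call = score_locus(query, target)
        assert (call.call, call.reason) == ("shared", "FULL_SPAN")

    def test_clean_preinsertion_site(self, locus):
        left, cr1, right, query = locus
        target = GenomeAssembly("t", {"x": left + right})
        call = score_locus(query, target)
        assert (call.call, call.reason) == ("absent", "CLEAN_PREINSERTION_SITE")
        assert call.target_gap is not None and call.target_gap <= 16

    @pytest.mark.parametrize("gap,expected_call", [(16, "absent"), (17, "unscorable")])
    def test_sixteen_bp_gap_boundary(self, locus, gap, expected_call):
        left, cr1, right, query = locus
        rng = np.random.default_rng(99)
        target = GenomeAssembly("t", {"x": left + random_dna(rng, gap) + right})
        call = score_locus(query, target)
        assert call.call == expected_call
        if expected_call == "unscorable":
            assert call.reason == "AMBIGUOUS_GAP"

    def test_multiple_flank_hits_unscorable(self, locus):
        """A segmental duplication of the 5' flank leaves two anchors."""
        left, cr1, right, query = locus
        dup = left[-700:]
        rng = np.random.default_rng(3)
        target = GenomeAssembly(
            "t", {"x": left + right + random_dna(rng, 2000) + dup}
        )
        call = score_locus(query, target)
        assert (call.call, call.reason) == ("unscorable", "MULTI_HIT")

    def test_missing_flank_unscorable(self, locus):
        left, cr1, right, query = locus
        rng = np.random.default_rng(4)
        target = GenomeAssembly("t", {"x": left + random_dna(rng, 2000)})
        call = score_locus(query, target)
        assert (call.call, call.reason) == ("unscorable", "NO_ANCHOR")

    def test_minus_strand_target(self, locus):
        left, cr1, right, query = locus
        target = GenomeAssembly("t", {"x": revcomp(left + right)})
        call = score_locus(query, target)
        assert call.call == "absent"

    def test_shared_with_diverged_interior(self, locus):
        """Flank anchors agree with the query gap: shared via the gap test
        even when the repeat interior is too diverged to align through."""
        left, cr1, right, query = locus
        rng = np.random.default_rng(5)
        scrambled = random_dna(rng, 300)  # same length, unalignable interior
        target = GenomeAssembly("t", {"x": left + scrambled + right})
        call = score_locus(query, target)
        assert call.call == "shared"
        assert call.reason in ("GAPPED_SHARED", "FULL_SPAN")

    def test_missing_target_species_errors(self, locus):
        from cr1kit.presence_absence import PresenceAbsenceScorer

        *_, query = locus
        scorer = PresenceAbsenceScorer({})
        with pytest.raises(KeyError):
            scorer.score(query, "nope")


class TestSweep:
    def test_single_distance_matches_score_locus(self, clean_sim):
        config, assemblies, truths = clean_sim
        copies = [
            _copy(t.loci["A"]) for t in truths[:30] if t.loci.get("A") is not None
        ]
        for c, t in zip(copies, [t for t in truths[:30] if t.loci.get("A")]):
            c.copy_id = t.insertion_id
        queries, _ = select_candidates(copies, assemblies["A"])
        queries = queries[:8]
        table = sweep_boundary_param(queries, assemblies["C"], [150])
        direct = [score_locus(q, assemblies["C"]) for q in queries]
        row = table.iloc[0]
        for call in CALLS:
            assert row[call] == sum(1 for c in direct if c.call == call)

    def test_empty_query_list(self, clean_sim):
        _, assemblies, _ = clean_sim
        table = sweep_boundary_param([], assemblies["C"], [50, 150])
        assert (table[list(CALLS)].to_numpy() == 0).all()

    def test_distances_required(self, clean_sim):
        _, assemblies, _ = clean_sim
        with pytest.raises(ValueError):
            sweep_boundary_param([], assemblies["C"], [])


class TestPartition:
    def test_every_pair_gets_exactly_one_call(self, clean_sim):
        from cr1kit.benchmark import score_truth_cohort

        config, assemblies, truths = clean_sim
        res = score_truth_cohort(assemblies, truths[:12], config.tree)
        n_pairs = res.n_insertions * (len(config.tree.leaves) - 1)
        assert len(res.calls) == n_pairs
        assert res.n_correct + res.n_wrong + res.n_unscorable == n_pairs
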