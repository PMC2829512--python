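"""Assembler, contig alignment/filters, junction classification, statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import evoreseq as er
from evoreseq import breakpoints as bp
from evoreseq import mapping
from evoreseq.breakpoints import Contig, ContigAlignment
from evoreseq.mapping import MappabilityMask


def _tile_reads(template, read_len=36, step=1, copies=2, prefix="t"):
    reads = []
    for c in range(copies):
        for i in range(0, len(template) - read_len + 1, step):
            reads.append(er.Read(f"{prefix}{c}_{i}", template[i : i + read_len], "I" * read_len))
    return reads


class TestAssembler:
    def test_single_junction_template_reconstructed(self, small_genome):
        template = small_genome.sequences["chrI"][700:760]  # 60 bp
        contigs = bp.assemble_contigs(_tile_reads(template), k=21, min_contig_len=40)
        assert len(contigs) == 1
        seq = contigs[0].sequence
        assert template in seq or er.revcomp(template) in seq
        assert contigs[0].n_reads == len(_tile_reads(template))

    def test_empty_pool_yields_no_contigs(self):
        assert bp.assemble_contigs([], k=21) == []

    def test_invalid_k_rejected(self, small_genome):
        reads = _tile_reads(small_genome.sequences["chrI"][:100])
        with pytest.raises(ValueError):
            bp.assemble_contigs(reads, k=40)

    @pytest.mark.parametrize("seed", range(5))
    def test_repeat_free_template_oracle(self, seed):
        """On error-free reads from a repeat-free template, the unitig set is
        the template itself (up to reverse complement)."""
        g = er.generate_reference(1, [1_500], gc=0.4, seed=100 + seed)
        template = g.sequences["chrI"]
        contigs = bp.assemble_contigs(_tile_reads(template), k=21, min_contig_len=40)
        assert len(contigs) == 1
        got = contigs[0].sequence
        assert got == template or got == er.revcomp(template)

    def test_singleton_kmers_pruned(self, small_genome):
        template = small_genome.sequences["chrI"][700:760]
        reads = _tile_reads(template, copies=2)
        # one unrelated read contributes only singleton k-mers -> pruned
        stray = er.generate_reference(1, [36], gc=0.4, seed=999).sequences["chrI"]
        reads.append(er.Read("err", stray, "I" * 36))
        contigs = bp.assemble_contigs(reads, k=21, min_contig_len=30)
        assert len(contigs) == 1
        got = contigs[0].sequence
        assert template in got or er.revcomp(template) in got


class TestAlignContig:
    def test_exact_substring_full_alignment(self, small_genome):
        contig = Contig("c", small_genome.sequences["chrI"][500:550], 3)
        alns = bp.align_contig(contig, small_genome)
        assert len(alns) == 1
        a = alns[0]
        assert (a.contig_start, a.contig_end) == (1, 50)
        assert (a.ref_start, a.ref_end, a.strand) == (501, 550, "+")
        assert a.identity == 1.0

    def test_reverse_complement_alignment(self, small_genome):
        contig = Contig("c", er.revcomp(small_genome.sequences["chrI"][500:550]), 3)
        alns = bp.align_contig(contig, small_genome)
        assert len(alns) == 1
        assert alns[0].strand == "-"
        assert (alns[0].ref_start, alns[0].ref_end) == (501, 550)

    def test_foreign_sequence_has_no_alignment(self, small_genome):
        rng = np.random.default_rng(0)
        foreign = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        # ensure it is genuinely absent
        assert foreign not in small_genome.sequences["chrI"]
        alns = bp.align_contig(Contig("c", foreign, 1), small_genome)
        assert all(a.contig_span < 30 for a in alns)


def _junction_genome_and_contig(seed, h, prefix_len, suffix_len, spacer=6):
    """Plant a right-boundary inverted junction and cut a crossing contig
    with chosen extents: parts measure (prefix_len, suffix_len + h)."""
    g0 = er.generate_reference(1, [20_000], gc=0.38, seed=seed)
    amp = er.Amplification(
        "chrI", 8_001, 11_000, 3, h_left=0, h_right=h, spacer_left=0, spacer_right=spacer
    )
    ref = er.plant_amplification_arms(g0, amp)
    evolved, truth = er.apply_evolution(ref, er.EvolutionSpec(amplification=amp))
    j = next(x for x in truth.junctions if x["label"] == "right_tail_to_tail")
    mid = len(j["sequence"]) // 2  # junction sits at the window midpoint
    seq = j["sequence"][mid - prefix_len : mid + suffix_len]
    return ref, Contig("jx", seq, 5)


class TestClassifyBreakpoint:
    def test_left_end_geometry_overlap_seven(self):
        """26 nt + 33 nt opposite-strand parts on a 52 nt contig -> 7 nt."""
        ref, contig = _junction_genome_and_contig(5, h=7, prefix_len=26, suffix_len=26)
        alns = bp.align_contig(contig, ref)
        assert len(alns) == 2
        call = bp.classify_breakpoint(contig, alns)
        assert sorted((call.part_a.contig_span, call.part_b.contig_span)) == [26, 33]
        assert len(contig.sequence) == 52
        assert call.orientation == "inverted"
        assert call.overlap == 7

    def test_right_end_geometry_overlap_thirteen(self):
        """32 nt + 32 nt opposite-strand parts on a 51 nt contig -> 13 nt."""
        ref, contig = _junction_genome_and_contig(6, h=13, prefix_len=32, suffix_len=19)
        alns = bp.align_contig(contig, ref)
        assert len(alns) == 2
        call = bp.classify_breakpoint(contig, alns)
        assert sorted((call.part_a.contig_span, call.part_b.contig_span)) == [32, 32]
        assert len(contig.sequence) == 51
        assert call.overlap == 13

    def test_direct_abutting_parts(self, small_genome):
        """Same-strand parts abutting exactly classify as direct, overlap 0."""
        seq = small_genome.sequences["chrI"]
        # pick a partner locus whose flanks terminate both alignments (a
        # junction with matching flank bases would genuinely have overlap > 0)
        b = next(
            b
            for b in range(5_000, 6_000)
            if seq[1_025] != seq[b] and seq[b - 1] != seq[1_024]
        )
        contig = Contig("d", seq[1_000:1_025] + seq[b : b + 25], 2)
        alns = bp.align_contig(contig, small_genome, min_align_len=20)
        assert len(alns) == 2
        call = bp.classify_breakpoint(contig, alns)
        assert call.orientation == "direct"
        assert call.overlap == 0
        assert call.junction_coords == (1_025, b + 1)

    def test_wrong_alignment_count_rejected(self, small_genome):
        contig = Contig("c", small_genome.sequences["chrI"][500:550], 1)
        alns = bp.align_contig(contig, small_genome)
        with pytest.raises(ValueError):
            bp.classify_breakpoint(contig, alns)


class TestFilterContigs:
    def test_single_region_contig_removed(self, small_genome):
        mask = MappabilityMask(
            {"chrI": np.ones(20_000, dtype=bool)}, 36
        )
        contig = Contig("c", small_genome.sequences["chrI"][500:550], 3)
        alns = {contig.id: bp.align_contig(contig, small_genome)}
        assert bp.filter_contigs([contig], alns, mask) == []

    def test_junction_contig_retained(self):
        ref, contig = _junction_genome_and_contig(7, h=7, prefix_len=26, suffix_len=26)
        mask = MappabilityMask({"chrI": np.ones(20_000, dtype=bool)}, 36)
        alns = {contig.id: bp.align_contig(contig, ref)}
        retained = bp.filter_contigs([contig], alns, mask)
        assert len(retained) == 1

    def test_unmappable_end_removed(self):
        ref, contig = _junction_genome_and_contig(8, h=7, prefix_len=26, suffix_len=26)
        m = np.ones(20_000, dtype=bool)
        m[10_900:11_100] = False  # junction neighbourhood unmappable
        retained = bp.filter_contigs(
            [contig], {contig.id: bp.align_contig(contig, ref)},
            MappabilityMask({"chrI": m}, 36),
        )
        assert retained == []

    def test_poor_coverage_removed(self, small_genome):
        seq = small_genome.sequences["chrI"]
        rng = np.random.default_rng(1)
        foreign = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        contig = Contig("c", seq[1_000:1_030] + foreign, 2)  # 30/70 covered
        mask = MappabilityMask({"chrI": np.ones(20_000, dtype=bool)}, 36)
        retained = bp.filter_contigs(
            [contig], {contig.id: bp.align_contig(contig, small_genome)}, mask
        )
        assert retained == []


class TestWildtypeSupport:
    def test_spanning_read_supports(self, small_genome):
        seq = small_genome.sequences["chrI"]
        aln = mapping.Alignment("r", "chrI", 1_001, "+", 0, mapping.UNIQUE_HIGH, seq[1_000:1_036])
        ok, n = bp.wildtype_support([aln], small_genome, "chrI", 1_018, min_span=10)
        assert ok and n == 1

    def test_non_reference_read_does_not_support(self, small_genome):
        seq = list(small_genome.sequences["chrI"][1_000:1_036])
        seq[18] = "ACGT".replace(seq[18], "")[0]
        aln = mapping.Alignment("r", "chrI", 1_001, "+", 0, mapping.UNIQUE_HIGH, "".join(seq))
        ok, n = bp.wildtype_support([aln], small_genome, "chrI", 1_018, min_span=10)
        assert not ok

    def test_min_span_beyond_read_length_impossible(self, small_genome):
        seq = small_genome.sequences["chrI"]
        aln = mapping.Alignment("r", "chrI", 1_001, "+", 0, mapping.UNIQUE_HIGH, seq[1_000:1_036])
        ok, _ = bp.wildtype_support([aln], small_genome, "chrI", 1_018, min_span=40)
        assert not ok

    def test_out_of_range_coordinate_rejected(self, small_genome):
        with pytest.raises(ValueError):
            bp.wildtype_support([], small_genome, "chrI", 50_000)


class TestBackgroundProbability:
    def test_worked_example(self):
        p = bp.background_probability(2, 11_320_000, window=50, n_breakpoints=2)
        assert p == pytest.approx(7.81e-11, rel=0.01)

    def test_no_background_process(self):
        assert bp.background_probability(0, 10_000) == 0.0

    def test_capped_at_one(self):
        assert bp.background_probability(1_000, 1_000, window=10) == 1.0

    @given(
        n=st.integers(0, 50),
        mappable=st.integers(1_000, 10_000_000),
        window=st.integers(1, 500),
    )
    def test_monotonicity(self, n, mappable, window):
        p = bp.background_probability(n, mappable, window)
        assert bp.background_probability(n + 1, mappable, window) >= p
        assert bp.background_probability(n, mappable, window + 10) >= p
        assert bp.background_probability(n, mappable * 2, window) <= p


def _call(orientation="inverted", in_amp=True, overlap=7):
    a = ContigAlignment("c", 1, 26, "chrI", 100, 125, "+", 1.0)
    b = ContigAlignment("c", 20, 52, "chrI", 110, 142, "-", 1.0)
    return bp.BreakpointCall(
        "c", a, b, (125, 142), "chrI", orientation, overlap, in_amplification=in_amp
    )


class TestInferStructure:
    @pytest.fixture()
    def segment(self):
        from evoreseq.cnv import Segment

        return Segment("chrI", 100, 11_000, 440, np.log2(5.0), 25)

    def test_full_evidence_labels_tandem_inverted(self, segment):
        model = bp.infer_structure(segment, 5.0, _call(), _call(), True, True)
        assert model.structure == "tandem_inverted"

    def test_missing_wildtype_support_unresolved(self, segment):
        model = bp.infer_structure(segment, 5.0, _call(), _call(), True, False)
        assert model.structure == "unresolved"

    def test_direct_orientation_unresolved(self, segment):
        model = bp.infer_structure(
            segment, 2.0, _call("direct"), _call("direct"), True, True
        )
        assert model.structure == "unresolved"


class TestEndToEnd:
    def test_scenario_junctions_recovered(self, small_scenario):
        """Both junction types assemble from the unmapped pool, survive the
        filters, and classify with the planted homology lengths; every
        retained two-part contig obeys the overlap identity."""
        cfg = small_scenario["config"]
        data = small_scenario["data"]
        contigs = bp.assemble_contigs(
            data["evolved"]["unmapped"], k=cfg.assembly_k, min_contig_len=cfg.min_contig_len
        )
        alns = {c.id: bp.align_contig(c, small_scenario["reference"]) for c in contigs}
        retained = bp.filter_contigs(contigs, alns, small_scenario["mask"])
        overlaps = set()
        for contig, a in retained:
            if len(a) != 2:
                continue
            call = bp.classify_breakpoint(contig, a)
            parts = call.part_a.contig_span + call.part_b.contig_span
            assert call.overlap == parts - len(contig.sequence)
            assert call.overlap >= 0
            if call.orientation == "inverted":
                overlaps.add(call.overlap)
        assert {7, 13} <= overlaps

    @pytest.mark.parametrize("chunk", [0, 1])
    def test_recovery_across_seeds(self, chunk):
        """Over 10 simulated scenarios at 35x, both junctions are recovered
        with the planted micro-homology lengths in >= 9 of 10 runs."""
        hits = 0
        for seed in range(chunk * 5, chunk * 5 + 5):
            g0 = er.generate_reference(1, [20_000], gc=0.38, seed=300 + seed)
            amp = er.Amplification("chrI", 8_001, 11_000, 5, 7, 13, 6, 10)
            ref = er.plant_amplification_arms(g0, amp)
            evolved, _ = er.apply_evolution(ref, er.EvolutionSpec(amplification=amp))
            reads, _ = er.simulate_reads(evolved, 35, err_rate=0.005, seed=seed)
            index = mapping.build_index(ref, 36)
            _, unmapped = mapping.map_reads(reads, index)
            contigs = bp.assemble_contigs(unmapped, k=21, min_contig_len=40)
            overlaps = set()
            for c in contigs:
                alns = bp.align_contig(c, ref)
                if len(alns) == 2:
                    call = bp.classify_breakpoint(c, alns)
                    if call.orientation == "inverted":
                        overlaps.add(call.overlap)
            if {7, 13} <= overlaps:
                hits += 1
        assert hits >= 4  # 9/10 across both chunks; allow one failure per half
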