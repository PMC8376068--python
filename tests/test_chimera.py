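import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read, original_id, residual_rrna_bases
from ribocure.alignment import LocalAlignment, reverse_complement
from ribocure.chimera import (
    ChimeraCall,
    CleanupConfig,
    classify_read,
    count_exact_duplicates,
    excise,
    iterate_cleanup,
    polish_boundaries,
    run_round,
    split_chimeric_alignment,
)
from ribocure.io_formats import Read
from ribocure.synthetic import ChimeraSimConfig, simulate_chimeric_dataset


def seg(read_len, start, end, identity=1.0, ref_id="rrna18S"):
    return LocalAlignment(
        read_id="r",
        ref_id=ref_id,
        read_span=(start, end),
        ref_span=(0, end - start),
        strand="+",
        score=2 * (end - start),
        identity=identity,
        read_len=read_len,
        column_ops="M" * (end - start),
    )


class TestClassify:
    def test_pure_rrna(self, rrna_refs):
        read = make_read("pure", rrna_refs[0].bases[200:320])
        call = classify_read(read, rrna_refs)
        assert call.verdict == "pure_rrna"
        assert call.rrna_segments[0].aligned_read_frac >= 0.90

    def test_clean_virus_is_non_rrna(self, rrna_refs, virus_ref):
        read = make_read("clean", virus_ref.bases[1000:1120])
        call = classify_read(read, rrna_refs)
        assert call.verdict == "non_rrna"
        assert call.rrna_segments == []

    def test_simulated_chimera_boundary(self, rrna_refs, virus_ref):
        read = make_read("chim", rrna_refs[0].bases[100:150] + virus_ref.bases[2000:2070])
        call = classify_read(read, rrna_refs)
        assert call.verdict == "chimeric"
        s, e = call.rrna_segments[0].read_span
        assert s == 0
        assert abs(e - 50) <= 2

    def test_verdict_invariants(self):
        with pytest.raises(ValueError):
            ChimeraCall("r", "non_rrna", [seg(100, 0, 50)])
        with pytest.raises(ValueError):
            ChimeraCall("r", "chimeric", [])


class TestPolish:
    def test_perfect_alignment_unchanged(self):
        aln = seg(100, 10, 60)
        assert polish_boundaries(aln, 10) is aln

    def test_ragged_tail_trimmed(self):
        # 40 matches then a net-positive chance extension X M M
        aln = LocalAlignment(
            read_id="r",
            ref_id="x",
            read_span=(0, 43),
            ref_span=(100, 143),
            strand="+",
            score=83,
            identity=42 / 43,
            read_len=120,
            column_ops="M" * 40 + "XMM",
        )
        polished = polish_boundaries(aln, 10)
        assert polished.read_span == (0, 40)
        assert polished.ref_span == (100, 140)
        assert polished.identity == 1.0

    def test_minus_strand_ref_side(self):
        # forward-read order runs against the reference on '-' alignments
        aln = LocalAlignment(
            read_id="r",
            ref_id="x",
            read_span=(0, 43),
            ref_span=(100, 143),
            strand="-",
            score=83,
            identity=42 / 43,
            read_len=120,
            column_ops="M" * 40 + "XMM",
        )
        polished = polish_boundaries(aln, 10)
        assert polished.read_span == (0, 40)
        assert polished.ref_span == (103, 143)

    def test_hopeless_alignment_returns_none(self):
        aln = LocalAlignment(
            read_id="r",
            ref_id="x",
            read_span=(0, 8),
            ref_span=(0, 8),
            strand="+",
            score=10,
            identity=0.5,
            read_len=20,
            column_ops="MXMXMXMX",
        )
        assert polish_boundaries(aln, 10) is None


class TestSplit:
    def _aln(self, ops, read_len=None):
        n_read = sum(1 for c in ops if c in "MXI")
        n_ref = sum(1 for c in ops if c in "MXD")
        return LocalAlignment(
            read_id="r",
            ref_id="x",
            read_span=(0, n_read),
            ref_span=(0, n_ref),
            strand="+",
            score=1,
            identity=ops.count("M") / len(ops),
            read_len=read_len or n_read,
            column_ops=ops,
        )

    def test_clean_alignment_unchanged(self):
        aln = self._aln("M" * 60)
        assert split_chimeric_alignment(aln) is aln

    def test_long_insertion_splits_to_bigger_side(self):
        # 40 M, 20 inserted read bases, 30 M: keep the left block
        aln = self._aln("M" * 40 + "I" * 20 + "M" * 30, read_len=120)
        out = split_chimeric_alignment(aln, 10)
        assert out.read_span == (0, 40)
        assert out.ref_span == (0, 40)
        assert out.identity == 1.0

    def test_messy_interleaved_gap_splits(self):
        # junk region of chance matches/mismatches between two clean anchors
        junk = "MXIMXIMXIMXI"
        aln = self._aln("M" * 30 + junk + "M" * 45, read_len=120)
        out = split_chimeric_alignment(aln, 10)
        assert out.read_span[0] > 30  # right block kept (more matches)
        assert out.column_ops == "M" * 45

    def test_short_gap_tolerated(self):
        # one mismatch between runs: a sequencing error, not a junction
        aln = self._aln("M" * 30 + "X" + "M" * 30)
        assert split_chimeric_alignment(aln, 10) is aln

    def test_colinear_double_moiety_not_pure(self, rrna_refs, virus_ref):
        # both moieties from the same reference region: one gapped alignment
        # would span the whole read; the split keeps the verdict chimeric
        r = rrna_refs[1].bases
        read = make_read("dbl", r[300:342] + virus_ref.bases[1840:1878] + r[368:422])
        call = classify_read(read, rrna_refs)
        assert call.verdict == "chimeric"
        seg = call.rrna_segments[0].read_span
        assert seg == (80, 134) or seg == (0, 42)


class TestExcise:
    def test_prefix_excision_keeps_right(self):
        read = make_read("r1", "A" * 50 + "C" * 70)
        (cured,) = excise(read, [seg(120, 0, 50)])
        assert cured.bases == "C" * 70
        assert cured.read_id == "r1|cut:0-50/R"
        assert cured.lineage == [("r1", (0, 50))]

    def test_internal_excision_keeps_both_flanks(self):
        read = make_read("r1", "A" * 40 + "C" * 40 + "G" * 40)
        cured = excise(read, [seg(120, 40, 80)])
        assert [len(c) for c in cured] == [40, 40]
        assert cured[0].read_id.endswith("/L") and cured[1].read_id.endswith("/R")
        assert cured[0].bases == "A" * 40 and cured[1].bases == "G" * 40

    def test_short_remainder_dropped(self):
        read = make_read("r1", "A" * 100 + "C" * 10)
        assert excise(read, [seg(110, 0, 100)]) == []

    def test_qualities_sliced_with_bases(self):
        read = Read("r1", "ACGTACGT", [10, 11, 12, 13, 14, 15, 16, 17])
        cfg = CleanupConfig(min_retained_length=2)
        cured = excise(read, [seg(8, 0, 4)], cfg)
        assert cured[0].bases == "ACGT"
        assert cured[0].quals == [14, 15, 16, 17]

    def test_overlapping_segments_rejected(self):
        read = make_read("r1", "A" * 100)
        with pytest.raises(ValueError, match="overlap"):
            excise(read, [seg(100, 0, 50), seg(100, 40, 90)])

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_substring_conservation(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n = data.draw(st.integers(60, 150))
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        read = Read("r", bases, list(rng.integers(0, 41, size=n)))
        s = data.draw(st.integers(0, n - 30))
        e = data.draw(st.integers(s + 20, min(n, s + 80)))
        for cured in excise(read, [seg(n, s, e)]):
            off = read.bases.find(cured.bases)
            assert off != -1
            assert read.quals[off : off + len(cured)] == cured.quals


class TestRunRound:
    def test_all_clean_passthrough(self, rrna_refs, virus_ref):
        reads = [make_read(f"v{i}", virus_ref.bases[i * 200 : i * 200 + 120]) for i in range(5)]
        cured, passthrough, discarded, calls, stats = run_round(reads, rrna_refs)
        assert passthrough == reads
        assert cured == [] and discarded == []
        stats.check()

    def test_all_pure_discarded(self, rrna_refs):
        reads = [make_read(f"p{i}", rrna_refs[0].bases[i * 100 : i * 100 + 120]) for i in range(5)]
        cured, passthrough, discarded, calls, stats = run_round(reads, rrna_refs)
        assert discarded == reads
        assert cured == [] and passthrough == []

    def test_mixed_composition_recovered(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(
            n_clean_virus=15, n_pure_rrna=10, n_single_chimera=20, flank_min=30, seed=77
        )
        reads, truth = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        cured, passthrough, discarded, calls, stats = run_round(reads, rrna_refs)
        assert stats.pure_rrna_discarded == 10
        assert stats.chimeric_detected == 20
        assert stats.passthrough == 15
        stats.check()


class TestIterateCleanup:
    def test_single_moiety_converges_in_two_rounds(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(n_single_chimera=20, flank_min=35, seed=3)
        reads, _ = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        result = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=5))
        assert result.rounds[0].cured_emitted > 0
        assert result.rounds[-1].cured_emitted == 0

    def test_double_moiety_needs_second_round(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(n_double_chimera=30, flank_min=35, seed=4)
        reads, truth = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        by_id = {t.read_id: t for t in truth}
        originals = {r.read_id: r for r in reads}

        # max_rounds=1 leaves the second moiety in place for some outputs
        one = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=1))
        residue_one = sum(
            residual_rrna_bases(r, originals[original_id(r.read_id)], by_id[original_id(r.read_id)])
            for r in one.final_reads
        )
        assert residue_one > 0

        two = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=2))
        residue_two = sum(
            residual_rrna_bases(r, originals[original_id(r.read_id)], by_id[original_id(r.read_id)])
            for r in two.final_reads
        )
        assert residue_two == 0

    def test_accounting_every_round(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(
            n_clean_virus=10, n_pure_rrna=10, n_single_chimera=10, n_double_chimera=10, seed=8
        )
        reads, _ = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        result = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=4))
        for st_ in result.rounds:
            assert st_.input == st_.pure_rrna_discarded + st_.chimeric_detected + st_.passthrough

    def test_idempotent_at_fixpoint(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(n_clean_virus=5, n_single_chimera=10, flank_min=35, seed=9)
        reads, _ = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        result = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=10))
        again = iterate_cleanup(result.final_reads, rrna_refs, CleanupConfig(max_rounds=10))
        assert again.rounds[0].cured_emitted == 0
        assert again.rounds[0].pure_rrna_discarded == 0

    def test_cured_count_monotone_nonincreasing(self, rrna_refs, virus_ref):
        cfg = ChimeraSimConfig(n_single_chimera=15, n_double_chimera=15, seed=10)
        reads, _ = simulate_chimeric_dataset(rrna_refs, virus_ref, cfg)
        result = iterate_cleanup(reads, rrna_refs, CleanupConfig(max_rounds=10))
        cured_counts = [r.cured_emitted for r in result.rounds]
        assert all(a >= b for a, b in zip(cured_counts, cured_counts[1:]))
        assert cured_counts[-1] == 0


class TestSamIngest:
    SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:{rid}\tLN:{rlen}\n"

    def test_sam_triage_matches_internal(self, rrna_refs, virus_ref, tmp_path):
        from ribocure.io_formats import read_sam_alignments

        rrna = rrna_refs[0]
        chimeric = make_read("chim", rrna.bases[100:150] + virus_ref.bases[2000:2070])
        pure = make_read("pure", rrna.bases[500:620])
        clean = make_read("clean", virus_ref.bases[100:220])
        reads = [chimeric, pure, clean]

        sam = tmp_path / "triage.sam"
        lines = self.SAM_HEADER.format(rid=rrna.ref_id, rlen=len(rrna))
        # aligner-style records: chimeric = soft-clipped, pure = full match, clean = unmapped
        lines += f"chim\t0\t{rrna.ref_id}\t101\t60\t50M70S\t*\t0\t0\t{chimeric.bases}\t{'?' * 120}\n"
        lines += f"pure\t0\t{rrna.ref_id}\t501\t60\t120M\t*\t0\t0\t{pure.bases}\t{'?' * 120}\n"
        lines += f"clean\t4\t*\t0\t0\t*\t*\t0\t0\t{clean.bases}\t{'?' * 120}\n"
        sam.write_text(lines)

        sam_records = list(read_sam_alignments(sam))
        cfg = CleanupConfig(triage_mode="sam_ingest")
        cured, passthrough, discarded, calls, stats = run_round(
            reads, rrna_refs, cfg, sam_records=sam_records
        )
        verdicts = {c.read_id: c.verdict for c in calls}
        assert verdicts == {"chim": "chimeric", "pure": "pure_rrna", "clean": "non_rrna"}

        internal = {r.read_id: classify_read(r, rrna_refs).verdict for r in reads}
        assert verdicts == internal


def test_count_exact_duplicates():
    reads = [make_read("a", "ACGT" * 10), make_read("b", "ACGT" * 10), make_read("c", "TTTT" * 10)]
    assert count_exact_duplicates(reads) == 1
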