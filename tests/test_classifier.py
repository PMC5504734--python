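"""QC, pre-filtering, fragment scanning, counting and frequency arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acescan._seq import reverse_complement
from acescan.classify import (
    ReadRecord,
    compute_q30,
    count_sites,
    prefilter_reads,
    read_fastx,
    read_sam,
    resistance_frequency,
    scan_read,
    scan_read_naive,
)
from acescan.profile import MutationRecord
from acescan.fragments import build_fragment_index, build_site_fragments
from acescan.reference import AceReference
from acescan.simulate import SimSite, SimulationSpec, simulate_reads


def make_read(seq, read_id="r1", q=None):
    quals = None if q is None else tuple([q] * len(seq))
    return ReadRecord(read_id=read_id, sequence=seq, qualities=quals)


class TestReadRecord:
    def test_quality_length_mismatch(self):
        with pytest.raises(ValueError):
            ReadRecord("r", "ACGT", (40, 40))


class TestComputeQ30:
    def test_all_high_quality_passes(self):
        report = compute_q30([make_read("ACGTACGT", q=40) for _ in range(10)])
        assert report.q30_fraction == 1.0
        assert report.passed and report.computable

    def test_half_low_quality_fails(self):
        reads = [make_read("ACGT", q=20), make_read("ACGT", q=40)]
        report = compute_q30(reads)
        assert report.q30_fraction == 0.5
        assert not report.passed

    def test_boundary_quality_counts_as_q30(self):
        report = compute_q30([make_read("AC", q=30)])
        assert report.q30_fraction == 1.0

    def test_threshold_is_inclusive(self):
        reads = [make_read("A" * 85, q=40), make_read("A" * 15, q=2)]
        assert compute_q30(reads, threshold=0.85).passed

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no reads"):
            compute_q30([])

    def test_missing_qualities_flagged_not_computable(self):
        report = compute_q30([make_read("ACGT")])
        assert not report.computable
        assert report.q30_fraction is None
        assert not report.passed


class TestResistanceFrequency:
    @pytest.mark.parametrize(
        "resistant,susceptible,expected",
        [(3, 7, 0.3), (0, 10, 0.0), (10, 0, 1.0), (0, 0, None), (1, 3, 0.25)],
    )
    def test_formula_and_zero_denominator(self, resistant, susceptible, expected):
        assert resistance_frequency(resistant, susceptible) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            resistance_frequency(-1, 2)


class TestScanRead:
    def test_resistant_fragment_substring_hit(self, mini_reference, mini_record):
        index = build_fragment_index([build_site_fragments(mini_reference, mini_record)])
        calls = scan_read(make_read("TTACCCAGCTTTAGG"), index)
        assert calls == [(index.site_ids[0], "resistant")]

    def test_reverse_complement_hit_is_identical(self, mini_reference, mini_record):
        index = build_fragment_index([build_site_fragments(mini_reference, mini_record)])
        calls = scan_read(make_read("GGTAAAGCTGGGTCC"), index)
        assert calls == [(index.site_ids[0], "resistant")]

    def test_read_without_fragments_yields_nothing(self, toy_index):
        assert scan_read(make_read("ACGT" * 30), toy_index) == []

    def test_read_with_both_alleles_is_ambiguous(self, toy_fragments, toy_index):
        chimera = toy_fragments.susceptible_fragment + toy_fragments.resistant_fragments[0]
        calls = scan_read(make_read(chimera), toy_index)
        assert calls == [(toy_fragments.site_id, "ambiguous")]

    def test_n_bases_never_match(self, toy_fragments, toy_index):
        seq = toy_fragments.susceptible_fragment.replace("G", "N", 1)
        assert scan_read(make_read(seq), toy_index) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        prefix=st.text(alphabet="ACGT", min_size=0, max_size=60),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_naive_scan_on_random_reads(self, toy_fragments, toy_index, prefix, seed):
        rng = np.random.default_rng(seed)
        insert = rng.choice(
            [toy_fragments.susceptible_fragment, toy_fragments.resistant_fragments[0], ""]
        )
        read = make_read(prefix + str(insert) + prefix[::-1])
        assert scan_read(read, toy_index) == scan_read_naive(read, toy_index)

    def test_strand_invariance_of_classification(self, toy_index, toy_reference):
        spec = SimulationSpec(
            reference=toy_reference,
            sites=[],
            n_reads=50,
            read_length=80,
            seed=11,
        )
        reads = simulate_reads(spec).reads
        for read in reads:
            flipped = make_read(reverse_complement(read.sequence), read.read_id)
            assert scan_read(read, toy_index) == scan_read(flipped, toy_index)


class TestCountSites:
    def test_tallies_and_frequency(self):
        calls = [[("s", "resistant")]] * 3 + [[("s", "susceptible")]] * 7
        (counts,) = count_sites(calls)
        assert (counts.resistant_reads, counts.susceptible_reads) == (3, 7)
        assert counts.resistance_frequency == pytest.approx(0.30)

    def test_zero_coverage_site_reports_none(self):
        (counts,) = count_sites([], site_ids=["site"])
        assert counts.resistance_frequency is None
        assert counts.susceptible_reads == 0

    def test_ambiguous_excluded_from_denominator(self):
        calls = [[("s", "resistant")], [("s", "susceptible")], [("s", "ambiguous")]]
        (counts,) = count_sites(calls)
        assert counts.ambiguous_reads == 1
        assert counts.resistance_frequency == 0.5

    def test_one_read_can_hit_several_sites(self):
        calls = [[("a", "resistant"), ("b", "susceptible")]]
        counts = {c.site_id: c for c in count_sites(calls)}
        assert counts["a"].resistant_reads == 1
        assert counts["b"].susceptible_reads == 1

    def test_order_independence(self, toy_reference, toy_record, toy_index):
        spec = SimulationSpec(
            reference=toy_reference,
            sites=[SimSite(record=toy_record, resistant_frequency=0.4)],
            n_reads=300,
            seed=5,
        )
        reads = simulate_reads(spec).reads
        forward = count_sites((scan_read(r, toy_index) for r in reads), toy_index.site_ids)
        backward = count_sites(
            (scan_read(r, toy_index) for r in reversed(reads)), toy_index.site_ids
        )
        assert forward == backward


class TestPrefilter:
    def test_exact_cds_substring_passes(self, toy_reference):
        read = make_read(toy_reference.cds[100:150])
        kept = list(prefilter_reads([read], [toy_reference]))
        assert kept == [read]

    def test_zero_shared_kmer_read_removed(self, toy_reference):
        # homopolymer absent from the synthetic CDS by construction
        read = make_read("A" * 50)
        assert "A" * 15 not in toy_reference.cds
        assert list(prefilter_reads([read], [toy_reference])) == []

    def test_reads_shorter_than_k_removed(self, toy_reference):
        assert list(prefilter_reads([make_read("ACGTACGT")], [toy_reference], k=15)) == []

    def test_simulated_reads_separated_from_background(self, toy_reference, toy_record):
        spec = SimulationSpec(
            reference=toy_reference,
            sites=[SimSite(record=toy_record, resistant_frequency=0.5)],
            n_reads=600,
            read_length=100,
            background_fraction=0.5,
            seed=42,
        )
        result = simulate_reads(spec)
        kept_ids = {
            r.read_id for r in prefilter_reads(result.reads, [toy_reference])
        }
        ace_ids = set(result.truth.loc[result.truth.origin == "ace", "read_id"])
        assert kept_ids == ace_ids

    def test_order_preserved(self, toy_reference):
        reads = [make_read(toy_reference.cds[i : i + 50], f"r{i}") for i in (0, 200, 40)]
        kept = list(prefilter_reads(reads, [toy_reference]))
        assert [r.read_id for r in kept] == ["r0", "r200", "r40"]


class TestIngestion:
    def test_fastq_round_trip(self, tmp_path):
        fq = tmp_path / "reads.fastq"
        fq.write_text("@r1\nACGTN\n+\nIIII#\n@r2\nGGCC\n+\n!!!!\n")
        reads = list(read_fastx(fq))
        assert [r.read_id for r in reads] == ["r1", "r2"]
        assert reads[0].sequence == "ACGTN"
        assert reads[0].qualities == (40, 40, 40, 40, 2)
        assert reads[1].qualities == (0, 0, 0, 0)

    def test_fasta_reads_have_no_qualities(self, tmp_path):
        fa = tmp_path / "reads.fasta"
        fa.write_text(">r1\nACGT\n")
        (read,) = list(read_fastx(fa))
        assert read.qualities is None

    def test_sam_ingestion_restores_read_orientation(self, tmp_path):
        sam = tmp_path / "reads.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:ref\tLN:100\n"
            "fwd\t0\tref\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIII\n"
            "rev\t16\tref\t1\t60\t8M\t*\t0\t0\tACGTACGT\tIIIIIIIH\n"
            "unmapped\t4\t*\t0\t0\t*\t*\t0\t0\tCCCC\tIIII\n"
        )
        reads = {r.read_id: r for r in read_sam(sam)}
        assert set(reads) == {"fwd", "rev"}
        assert reads["fwd"].sequence == "ACGTACGT"
        # reverse-strand SEQ is reference-oriented; restore read orientation
        assert reads["rev"].sequence == reverse_complement("ACGTACGT")
        assert reads["rev"].qualities == (39,) + (40,) * 7
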