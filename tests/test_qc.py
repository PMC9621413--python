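"""Sequencing QC funnel, frequency grids, and stop statistics."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from splintlig.assembly_sim import ReadSimConfig, sample_library_reads
from splintlig.qc import (
    deduplicate,
    emit_report,
    filter_full_length,
    frequency_grids,
    load_report,
    merge_pairs,
    run_qc,
    stop_statistics,
)


def rec(seq, name="r", q=30):
    r = SeqRecord(Seq(seq), id=name, description="")
    r.letter_annotations["phred_quality"] = [q] * len(seq)
    return r


class TestMergePairs:
    def test_identical_fully_overlapping_mates(self):
        s = "ACGTACGTACGTACGTACGTACGT"
        from splintlig.thermo import revcomp

        merged, dropped = merge_pairs([rec(s)], [rec(revcomp(s))], min_overlap=10)
        assert dropped == 0
        assert str(merged[0].seq) == s

    def test_zero_overlap_pair_dropped_and_counted(self):
        merged, dropped = merge_pairs(
            [rec("A" * 30)], [rec("C" * 30)], min_overlap=10
        )
        assert merged == []
        assert dropped == 1

    def test_length_mismatched_inputs_error(self):
        with pytest.raises(ValueError, match="differ in length"):
            merge_pairs([rec("ACGT" * 10)], [])

    def test_synthetic_pairs_merge_to_truth_insert(self, template):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=100, base_mix_bias=None, layout="paired", seed=6)
        )
        merged, dropped = merge_pairs(res.r1, res.r2, min_overlap=20)
        assert dropped == 0
        orf_s = template.orf_span[0]
        for m in merged:
            i = int(m.id.removeprefix("read"))
            s = str(m.seq)
            assert len(s) == template.length
            for ci, _ in template.randomized_codons:
                assert s[orf_s + 3 * ci : orf_s + 3 * ci + 3] == res.truth.loc[i, f"codon_{ci}"]

    def test_consensus_takes_higher_quality_base(self):
        from splintlig.thermo import revcomp

        s = "ACGTACGTACGTACGTACGT"
        # mate 2 has a mismatch in the overlap but higher quality there
        s2 = s[:10] + "T" + s[11:]
        assert s[10] != "T"
        r1 = rec(s, q=20)
        r2 = rec(revcomp(s2), q=30)
        merged, _ = merge_pairs([r1], [r2], min_overlap=10, max_mismatch_frac=0.2)
        assert str(merged[0].seq)[10] == "T"


class TestDeduplicate:
    def test_copies_collapse_to_first(self):
        reads = [rec("ACGT", f"r{i}") for i in range(5)]
        unique, removed = deduplicate(reads)
        assert len(unique) == 1
        assert unique[0].id == "r0"
        assert removed == 4

    def test_distinct_input_unchanged(self):
        reads = [rec("ACGT"), rec("TTTT"), rec("GGGG")]
        unique, removed = deduplicate(reads)
        assert len(unique) == 3
        assert removed == 0

    def test_multiset_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(17)
        pool = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(40)]
        reads = [rec(str(rng.choice(pool)), f"r{i}") for i in range(300)]
        unique, removed = deduplicate(reads)
        # hash-free oracle: quadratic scan
        oracle = []
        for r in reads:
            if not any(str(r.seq) == str(u.seq) for u in oracle):
                oracle.append(r)
        assert len(unique) == len(oracle)
        assert removed == 300 - len(oracle)


class TestLengthFilter:
    def test_exact_and_tolerant_filtering(self):
        reads = [rec("A" * n) for n in (98, 99, 100, 101, 103)]
        assert len(filter_full_length(reads, 100)) == 1
        assert len(filter_full_length(reads, 100, tolerance=1)) == 3
        assert len(filter_full_length(reads, 100, tolerance=100)) == 5

    def test_bad_expected_length_rejected(self):
        with pytest.raises(ValueError):
            filter_full_length([], 0)


class TestFrequencyGrids:
    def test_single_read_gives_indicator_grid(self, template):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=1, base_mix_bias=None, seed=1)
        )
        report = frequency_grids(res.reads, template)
        assert report.nt_grid.shape == (60, 5)  # 20 codons × 3 positions; symbol + ACGT
        freqs = report.nt_grid[list("ACGT")]
        assert ((freqs == 0) | (freqs == 1)).all().all()
        assert freqs.sum(axis=1).tolist() == pytest.approx([1.0] * 60)

    def test_rows_sum_to_one_and_k_positions_exclude_ac(self, template):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=2000, base_mix_bias=None, seed=2)
        )
        report = frequency_grids(res.reads, template)
        freqs = report.nt_grid[list("ACGT")]
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)
        k_rows = freqs.xs(3, level="position")
        assert (k_rows["A"] == 0).all() and (k_rows["C"] == 0).all()

    def test_uniform_simulation_recovers_quarter_frequencies(self, template):
        n = 20_000
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=n, base_mix_bias=None, seed=3)
        )
        report = frequency_grids(res.reads, template)
        pooled = n * 20
        for pos, expected in ((1, 0.25), (2, 0.25), (3, 0.5)):
            row = report.nt_avg.loc[pos]
            bases = "ACGT" if pos < 3 else "GT"
            se = math.sqrt(expected * (1 - expected) / pooled)
            for b in bases:
                assert row[f"{b}_mean"] == pytest.approx(expected, abs=3 * se)

    def test_unanchored_reads_excluded_and_counted(self, template):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=10, base_mix_bias=None, seed=4)
        )
        corrupted = rec("T" * template.length, "bad")
        report = frequency_grids(res.reads + [corrupted], template)
        assert report.stage_counts == {"full_length": 11, "anchored": 10}


class TestStopStatistics:
    def test_constant_orf_has_no_stops(self):
        from helpers import make_template as mk

        t = mk(30, [], five_prime=12, three_prime=9)
        res = sample_library_reads(t, ReadSimConfig(n_reads=50, base_mix_bias=None, seed=5))
        stats = stop_statistics(res.reads, t)
        assert stats["observed"] == 0.0
        assert stats["expected_linear"] == 0.0
        assert stats["expected_exact"] == 0.0

    def test_tag_suppression_decreases_stop_fraction(self, template):
        observed = []
        for g_freq in (0.5, 0.25, 0.1):
            bias = {
                "N": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
                "K": {"A": 0.0, "C": 0.0, "G": g_freq, "T": 1 - g_freq},
            }
            res = sample_library_reads(
                template, ReadSimConfig(n_reads=5000, base_mix_bias=bias, seed=7)
            )
            observed.append(stop_statistics(res.reads, template)["observed"])
        assert observed[0] > observed[1] > observed[2]

    def test_empty_input_rejected(self, template):
        with pytest.raises(ValueError):
            stop_statistics([], template)


class TestFunnelAndReport:
    def test_funnel_monotone_on_mixed_input(self, template):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=200, base_mix_bias=None, seed=8)
        )
        reads = (
            res.reads
            + res.reads[:50]  # duplicates
            + [rec("ACGT" * 10, "short")]  # wrong length
            + [rec("T" * template.length, "unanchored")]
        )
        report = run_qc(template, merged=reads)
        counts = list(report.stage_counts.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert report.stage_counts["total_reads"] == 252
        assert report.stage_counts["deduplicated"] == 202
        assert report.stage_counts["full_length"] == 201
        assert report.stage_counts["anchored"] == 200

    def test_report_round_trip(self, template, tmp_path):
        res = sample_library_reads(
            template, ReadSimConfig(n_reads=500, base_mix_bias=None, seed=9)
        )
        report = run_qc(template, merged=res.reads)
        emit_report(report, tmp_path)
        back = load_report(tmp_path)
        assert back.stage_counts == report.stage_counts
        assert back.stop_containing_fraction == report.stop_containing_fraction
        assert np.allclose(
            back.nt_grid[list("ACGT")].values, report.nt_grid[list("ACGT")].values
        )
        assert np.allclose(back.aa_table.values, report.aa_table.values)

    def test_empty_funnel_report(self, template, tmp_path):
        report = run_qc(template, merged=[rec("ACGT", "only")])
        assert report.stage_counts["full_length"] == 0
        paths = emit_report(report, tmp_path)
        assert paths["funnel"].exists()
        back = load_report(tmp_path)
        assert back.nt_grid is None
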