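"""Read-length/start sampling, the error process, and read generation."""

import numpy as np
import pytest
from scipy import stats

from svsimkit import (DepthProfile, DepthWindow, ErrorProfile, ReadSimConfig,
                      corrupt_sequence, make_toy_genome, sample_read_length,
                      sample_read_start, simulate_reads, train_profile,
                      write_fastq)
from svsimkit.readsim import edit_counts, ops_to_cigar


class TestReadLength:
    def test_degenerate_range_is_constant(self, rng):
        cfg = ReadSimConfig(coverage=1, median_length=1000, length_range=(1000, 1000))
        assert all(sample_read_length(cfg, rng) == 1000 for _ in range(20))

    def test_sample_median_tracks_requested_median(self, rng):
        cfg = ReadSimConfig(coverage=1, median_length=25_000,
                            length_range=(2_000, 100_000))
        draws = [sample_read_length(cfg, rng) for _ in range(50_000)]
        assert abs(np.median(draws) / 25_000 - 1) < 0.02
        assert min(draws) >= 2_000 and max(draws) <= 100_000

    def test_asymmetric_range_keeps_median(self, rng):
        cfg = ReadSimConfig(coverage=1, median_length=25_000,
                            length_range=(1_000, 30_000))
        draws = [sample_read_length(cfg, rng) for _ in range(50_000)]
        assert abs(np.median(draws) / 25_000 - 1) < 0.02

    def test_deterministic_sequence_for_fixed_seed(self):
        cfg = ReadSimConfig(coverage=1, median_length=5000, length_range=(1000, 20000))
        a = [sample_read_length(cfg, np.random.default_rng(3)) for _ in range(100)]
        b = [sample_read_length(cfg, np.random.default_rng(3)) for _ in range(100)]
        assert a == b


class TestReadStart:
    def test_uniform_starts_pass_chi_square(self, rng):
        starts = [sample_read_start(10_000, 1, rng) for _ in range(20_000)]
        counts, _ = np.histogram(starts, bins=10, range=(1, 10_001))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_window_depth_ratio_respected(self, rng):
        windows = [DepthWindow("chr1", 1, 5000, 10.0),
                   DepthWindow("chr1", 5001, 10_000, 30.0)]
        starts = np.array([sample_read_start(10_000, 100, rng, windows)
                           for _ in range(40_000)])
        ratio = (starts > 5000).sum() / (starts <= 5000).sum()
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_zero_depth_window_gets_no_starts(self, rng):
        windows = [DepthWindow("chr1", 1, 5000, 10.0),
                   DepthWindow("chr1", 5001, 10_000, 0.0)]
        starts = [sample_read_start(10_000, 100, rng, windows) for _ in range(2000)]
        assert max(starts) <= 5000

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DepthProfile([DepthWindow("chr1", 1, 5000, 1.0),
                          DepthWindow("chr1", 4000, 9000, 2.0)]).validate()


class TestCorrupt:
    def test_zero_profile_is_identity(self, rng):
        prof = ErrorProfile.uniform(sub=0, ins=0, dele=0)
        read, ops = corrupt_sequence("ACGTACGTACGT", prof, rng)
        assert read == "ACGTACGTACGT" and ops == []

    def test_certain_substitution_replaces_every_base(self, rng):
        prof = ErrorProfile.uniform(sub=1.0, ins=0.0, dele=0.0)
        template = "ACGT" * 25
        read, ops = corrupt_sequence(template, prof, rng)
        assert len(read) == len(template)
        assert all(a != b for a, b in zip(read, template))
        assert sum(1 for o in ops if o[0] == "sub") == len(template)

    def test_empirical_rates_match_profile_within_3_sigma(self, rng):
        """Uniform 5%/2%/3% rates over ~1e6 template bases."""
        p_sub, p_ins, p_del = 0.05, 0.02, 0.03
        prof = ErrorProfile.uniform(sub=p_sub, ins=p_ins, dele=p_del,
                                    del_length_dist=[0.5, 0.5])
        n_sub = n_ins = n_del_events = 0
        decisions = aligned = 0
        for _ in range(100):
            template = "".join(rng.choice(list("ACGT"), 10_000))
            _, ops = corrupt_sequence(template, prof, rng)
            s, i, d = edit_counts(ops)
            dels = [o for o in ops if o[0] == "del"]
            n_sub += s
            n_ins += sum(1 for o in ops if o[0] == "ins")
            n_del_events += len(dels)
            interior = d - len(dels)
            decisions += 10_000 - interior
            aligned += 10_000 - d
        for events, denom, p in ((n_del_events, decisions, p_del),
                                 (n_sub, decisions, p_sub),
                                 (n_ins, aligned, p_ins)):
            se = np.sqrt(p * (1 - p) / denom)
            assert abs(events / denom - p) < 3 * se

    def test_edit_list_reconstructs_cigar_lengths(self, rng):
        prof = ErrorProfile.synthetic(seed=2)
        template = "".join(rng.choice(list("ACGT"), 5000))
        read, ops = corrupt_sequence(template, prof, rng)
        cigar = ops_to_cigar(ops, len(template))
        ref_consumed = sum(l for op, l in cigar if op in "MD")
        query_consumed = sum(l for op, l in cigar if op in "MI")
        assert ref_consumed == len(template)
        assert query_consumed == len(read)


class TestSimulateReads:
    def test_coverage_accounting(self):
        genome = make_toy_genome(1, 100_000, seed=3)
        prof = ErrorProfile.synthetic(seed=1)
        cfg = ReadSimConfig(coverage=20, median_length=2000,
                            length_range=(1000, 4000), seed=8)
        reads = simulate_reads(genome, prof, cfg)
        total = sum(r.template_length for r in reads)
        assert 1.9e6 <= total <= 2.1e6

    def test_accuracy_override_sets_mean_identity(self):
        genome = make_toy_genome(1, 50_000, seed=3)
        prof = ErrorProfile.synthetic(seed=1)
        cfg = ReadSimConfig(coverage=10, median_length=2000,
                            length_range=(1000, 4000),
                            accuracy_override=0.99, seed=8)
        reads = simulate_reads(genome, prof, cfg)
        mean_identity = np.mean([r.identity for r in reads])
        assert mean_identity == pytest.approx(0.99, abs=0.01)

    def test_byte_identical_fastq_for_fixed_seed(self, tmp_path):
        genome = make_toy_genome(1, 20_000, seed=3)
        prof = ErrorProfile.synthetic(seed=1)
        cfg = ReadSimConfig(coverage=5, median_length=2000,
                            length_range=(1000, 4000), seed=4)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            reads = simulate_reads(genome, prof, cfg)
            write_fastq(reads, tmp_path / name, profile=prof)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_both_haplotypes_sampled(self):
        genome = make_toy_genome(1, 20_000, seed=3)
        haps = {"hap1": genome, "hap2": genome}
        prof = ErrorProfile.uniform(sub=0.01, ins=0, dele=0)
        cfg = ReadSimConfig(coverage=10, median_length=1000,
                            length_range=(500, 2000), seed=4)
        reads = simulate_reads(haps, prof, cfg)
        labels = {r.haplotype for r in reads}
        assert labels == {"hap1", "hap2"}
        frac = np.mean([r.haplotype == "hap1" for r in reads])
        assert 0.4 < frac < 0.6

    def test_zero_coverage_is_empty(self):
        genome = make_toy_genome(1, 20_000, seed=3)
        cfg = ReadSimConfig(coverage=0, median_length=1000, length_range=(500, 2000))
        assert simulate_reads(genome, ErrorProfile.synthetic(), cfg) == []

    def test_perfect_truth_alignments_retrain_cleanly(self):
        """Strand-aware truth alignments feed the trainer without artifacts."""
        genome = make_toy_genome(1, 60_000, seed=13)
        prof = ErrorProfile.uniform(sub=0.04, ins=0.015, dele=0.02,
                                    ins_length_dist=[0.7, 0.3],
                                    del_length_dist=[0.6, 0.4])
        cfg = ReadSimConfig(coverage=40, median_length=3000,
                            length_range=(1500, 6000), seed=21)
        reads = simulate_reads(genome, prof, cfg)
        assert {r.strand for r in reads} == {"+", "-"}
        trained = train_profile((r.to_alignment() for r in reads), genome)
        assert np.abs(trained.sub_rate.mean() - 0.04) < 0.003
        assert np.abs(trained.ins_rate.mean() - 0.015) < 0.002
        assert np.abs(trained.del_rate.mean() - 0.02) < 0.002
        assert len(trained.del_length_dist) == 2
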