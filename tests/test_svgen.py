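"""Random SV generation and application to haplotypes."""

import numpy as np
import pytest
from scipy import stats

from svsimkit import (PlacementError, SVEvent, SVSimConfig, apply_svs,
                      generate_random_svs, parse_truth_vcf, write_truth_vcf)
from svsimkit.events import Genotype, SVType


def _ev(sv_type, start, length, *, ref_span=-1, seq="", gt=Genotype.HOM,
        copies=1, chrom="chr1", **kw):
    return SVEvent(id=f"{sv_type}@{start}", chrom=chrom, start=start,
                   sv_type=sv_type, length=length, ref_span=ref_span,
                   inserted_seq=seq, copies=copies, genotype=gt, **kw)


class TestApply:
    """Hand-computed rearrangement outcomes on toy sequences (toy mode)."""

    @pytest.mark.parametrize("ref,event,expected", [
        ("AACCGGTTAA", _ev(SVType.DEL, 3, 4), "AATTAA"),
        ("AAAAA", _ev(SVType.INS, 2, 3, ref_span=0, seq="GGG"), "AAGGGAAA"),
        ("ATCGTTTT", _ev(SVType.DUP, 1, 4), "ATCGATCGTTTT"),
        ("ATCGTTTT", _ev(SVType.INVDUP, 1, 4), "ATCGCGATTTTT"),
        # reverse-complement palindrome: inversion is the identity
        ("AACGTT", _ev(SVType.INV, 2, 4), "AACGTT"),
        ("AACCGGTTAA", _ev(SVType.CSUB, 3, 5, ref_span=4, seq="TTTTT"), "AATTTTTTTAA"),
    ])
    def test_single_event(self, ref, event, expected):
        out = apply_svs({"chr1": ref}, [event], min_length=1)
        assert out["merged"]["chr1"] == expected

    def test_reciprocal_translocation_swaps_tails(self):
        ref = {"chr1": "AAAATTTT", "chr2": "CCCCGGGG"}
        ev = _ev(SVType.TRA, 5, 4, ref_span=0, partner_chrom="chr2", partner_start=5)
        out = apply_svs(ref, [ev], min_length=1)
        assert out["merged"]["chr1"] == "AAAAGGGG"
        assert out["merged"]["chr2"] == "CCCCTTTT"
        assert sum(map(len, out["merged"].values())) == sum(map(len, ref.values()))

    def test_het_events_touch_one_haplotype(self):
        ref = {"chr1": "A" * 200}
        events = [_ev(SVType.DEL, 10, 20, gt=Genotype.HET_H1),
                  _ev(SVType.DEL, 100, 30, gt=Genotype.HET_H2),
                  _ev(SVType.DEL, 150, 10, gt=Genotype.HOM)]
        out = apply_svs(ref, events, min_length=1)
        assert len(out["hap1"]["chr1"]) == 200 - 20 - 10
        assert len(out["hap2"]["chr1"]) == 200 - 30 - 10
        assert len(out["merged"]["chr1"]) == 200 - 60

    def test_overlapping_events_rejected(self):
        ref = {"chr1": "A" * 200}
        with pytest.raises(Exception, match="overlap"):
            apply_svs(ref, [_ev(SVType.DEL, 10, 50), _ev(SVType.DEL, 30, 50)],
                      min_length=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_length_bookkeeping_exact(self, toy_genome, seed):
        """Output length == reference length + signed per-event delta, exactly."""
        cfg = SVSimConfig(counts_by_type={SVType.DEL: 4, SVType.INS: 4,
                                          SVType.DUP: 2, SVType.INVDUP: 2,
                                          SVType.INV: 2, SVType.CSUB: 2},
                          default_length_range=(50, 300),
                          telomere_window_bp=3000, seed=seed)
        events = generate_random_svs(cfg, toy_genome)
        out = apply_svs(toy_genome, events)
        ref_total = sum(map(len, toy_genome.values()))
        for label, gts in (("hap1", (Genotype.HET_H1, Genotype.HOM)),
                           ("hap2", (Genotype.HET_H2, Genotype.HOM))):
            delta = sum(e.length_delta for e in events if e.genotype in gts)
            assert sum(map(len, out[label].values())) == ref_total + delta
        assert sum(map(len, out["merged"].values())) == \
            ref_total + sum(e.length_delta for e in events)


class TestGenerate:
    def test_deterministic_under_fixed_seed(self, toy_genome):
        cfg = SVSimConfig(counts_by_type={SVType.DEL: 5, SVType.INS: 5},
                          telomere_window_bp=3000,
                          default_length_range=(50, 200), seed=1)
        a = generate_random_svs(cfg, toy_genome)
        b = generate_random_svs(cfg, toy_genome)
        assert [(e.chrom, e.start, e.length, e.genotype) for e in a] == \
               [(e.chrom, e.start, e.length, e.genotype) for e in b]

    def test_requested_counts_respected(self, toy_events):
        counts = {}
        for e in toy_events:
            counts[e.sv_type] = counts.get(e.sv_type, 0) + 1
        assert counts == {SVType.DEL: 6, SVType.INS: 6, SVType.DUP: 3,
                          SVType.INV: 3, SVType.CSUB: 3}

    def test_unbiased_placement_matches_uniform(self):
        """weight=1: telomeric fraction within the binomial CI of its mass."""
        genome = {"chr1": "ACGT" * 125_000}  # 500 kb
        window = 10_000
        cfg = SVSimConfig(counts_by_type={SVType.INS: 2000},
                          default_length_range=(50, 60),
                          telomere_window_bp=window, telomere_weight=1.0, seed=3)
        events = generate_random_svs(cfg, genome)
        u = 2 * window / 500_000
        frac = np.mean([e.start <= window or e.start > 500_000 - window
                        for e in events])
        lo, hi = stats.binom.interval(0.999, 2000, u)
        assert lo / 2000 <= frac <= hi / 2000

    def test_telomere_weight_enriches_as_mixture_predicts(self):
        """weight=5 on 1 Mb: fraction ~= w*u / (1 + (w-1)*u)."""
        genome = {"chr1": "ACGT" * 250_000}  # 1 Mb
        window, weight, n = 10_000, 5.0, 2000
        cfg = SVSimConfig(counts_by_type={SVType.INS: n},
                          default_length_range=(50, 60),
                          telomere_window_bp=window, telomere_weight=weight, seed=9)
        events = generate_random_svs(cfg, genome)
        u = 2 * window / 1_000_000
        expected = weight * u / (1 + (weight - 1) * u)
        frac = np.mean([e.start <= window or e.start > 1_000_000 - window
                        for e in events])
        lo, hi = stats.binom.interval(0.999, n, expected)
        assert lo / n <= frac <= hi / n

    def test_impossible_placement_fails_loudly(self):
        genome = {"chr1": "ACGT" * 2500}  # 10 kb
        cfg = SVSimConfig(counts_by_type={SVType.DEL: 100},
                          default_length_range=(5000, 5000),
                          telomere_window_bp=1000, seed=1)
        with pytest.raises(PlacementError):
            generate_random_svs(cfg, genome)


class TestTruthVcf:
    def test_anchor_base_encoding_of_deletion(self, tmp_path):
        ref = {"chr1": "AACCGGTTAA"}
        ev = _ev(SVType.DEL, 3, 4)
        path = tmp_path / "t.vcf"
        write_truth_vcf([ev], ref, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[0], fields[1], fields[3], fields[4]) == ("chr1", "2", "ACCGG", "A")

    def test_homozygous_genotype_written_as_1_1(self, tmp_path):
        ref = {"chr1": "A" * 200}
        path = tmp_path / "t.vcf"
        write_truth_vcf([_ev(SVType.DEL, 50, 60)], ref, path)
        assert "1|1" in path.read_text()

    def test_vcf_round_trip_preserves_events(self, tmp_path, toy_genome):
        cfg = SVSimConfig(counts_by_type={SVType.DEL: 20, SVType.INS: 20,
                                          SVType.DUP: 15, SVType.INVDUP: 15,
                                          SVType.INV: 15, SVType.CSUB: 10,
                                          SVType.TRA: 1},
                          default_length_range=(50, 300),
                          telomere_window_bp=3000, het_fraction=0.6, seed=2)
        events = generate_random_svs(cfg, toy_genome)
        assert len(events) == 96
        path = tmp_path / "truth.vcf"
        write_truth_vcf(events, toy_genome, path)
        back = {e.id: e for e in parse_truth_vcf(
            path, {c: len(s) for c, s in toy_genome.items()})}
        assert len(back) == len(events)
        for e in events:
            r = back[e.id]
            assert (e.chrom, e.start, e.sv_type, e.length, e.ref_span,
                    e.inserted_seq, e.copies, e.genotype,
                    e.partner_chrom, e.partner_start) == \
                   (r.chrom, r.start, r.sv_type, r.length, r.ref_span,
                    r.inserted_seq, r.copies, r.genotype,
                    r.partner_chrom, r.partner_start)
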