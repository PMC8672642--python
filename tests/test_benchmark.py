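"""Call filtering, truth matching, per-call scoring and summary metrics."""

import pytest

from svsimkit import (BenchmarkConfig, CallRecord, MatchResult, SVEvent,
                      benchmark_calls, calls_from_truth, compute_metrics,
                      filter_calls, match_calls, score_call)
from svsimkit.events import Genotype, SVType


def _truth(start=10_000, length=500, sv_type=SVType.DEL, gt=Genotype.HOM,
           chrom="chr1", ident="t"):
    return SVEvent(id=ident, chrom=chrom, start=start, sv_type=sv_type,
                   length=length, genotype=gt)


def _call(pos=10_000, length=500, sv_type="DEL", gt="hom", support=10,
          filt="PASS", chrom="chr1", caller="x"):
    return CallRecord(caller=caller, chrom=chrom, pos=pos, length=length,
                      sv_type=sv_type, genotype=gt, support=support, filter=filt)


CFG = BenchmarkConfig()


class TestFilter:
    @pytest.mark.parametrize("call,kept", [
        (_call(length=49, support=10), False),        # below the 50 bp floor
        (_call(length=500, support=2), False),        # under-supported
        (_call(length=500, support=10, filt="q5"), False),  # non-PASS filter
        (_call(length=500, support=3), True),
        (_call(length=0, support=10), True),          # undetermined length kept
        (_call(length=500, support=10, filt="."), True),    # '.' counts as PASS
        (_call(length=500, support=None), True),      # no support field reported
    ])
    def test_retention_rules(self, call, kept):
        assert (filter_calls([call], CFG) == [call]) is kept

    def test_support_threshold_scales_with_depth(self):
        assert BenchmarkConfig.min_support_for_depth(20) == 3
        assert BenchmarkConfig.min_support_for_depth(30) == 5


class TestMatch:
    def test_match_within_window_and_margin(self):
        matches, fp, fn = match_calls([_call(pos=10_800, length=600)],
                                      [_truth(10_000, 500)], CFG)
        assert len(matches) == 1 and not fp and not fn

    def test_position_outside_window_is_fp_and_fn(self):
        matches, fp, fn = match_calls([_call(pos=12_000, length=500)],
                                      [_truth(10_000, 500)], CFG)
        assert not matches and len(fp) == 1 and len(fn) == 1

    def test_short_sv_requires_exact_length(self):
        matches, fp, fn = match_calls([_call(pos=10_010, length=101)],
                                      [_truth(10_000, 100)], CFG)
        assert not matches
        relaxed = BenchmarkConfig(short_len_margin=0.35)
        matches, _, _ = match_calls([_call(pos=10_010, length=101)],
                                    [_truth(10_000, 100)], relaxed)
        assert len(matches) == 1

    def test_type_and_genotype_never_gate_matching(self):
        matches, _, _ = match_calls([_call(sv_type="INS", gt="het")],
                                    [_truth(sv_type=SVType.DEL)], CFG)
        assert len(matches) == 1
        assert not matches[0].type_correct and not matches[0].gt_correct

    def test_undetermined_length_matches_on_position(self):
        matches, _, _ = match_calls([_call(length=0, sv_type="BND")],
                                    [_truth(10_000, 500)], CFG)
        assert len(matches) == 1
        assert matches[0].score == pytest.approx(0.4 + 0.2)  # pos + gt only

    def test_one_to_one_nearest_assignment(self):
        truth = [_truth(10_000, 500, ident="a"), _truth(10_900, 500, ident="b")]
        calls = [_call(pos=10_050), _call(pos=10_890)]
        matches, fp, fn = match_calls(calls, truth, CFG)
        assert len(matches) == 2 and not fp and not fn
        pairing = {m.truth.id: m.call.pos for m in matches}
        assert pairing == {"a": 10_050, "b": 10_890}

    def test_translation_invariance(self):
        shift = 123_456
        truth = [_truth(10_000 + shift, 500)]
        calls = [_call(pos=10_800 + shift, length=600)]
        matches, _, _ = match_calls(calls, truth, CFG)
        base, _, _ = match_calls([_call(pos=10_800, length=600)],
                                 [_truth(10_000, 500)], CFG)
        assert matches[0].score == base[0].score

    def test_conservation_of_counts(self, toy_events):
        calls = calls_from_truth(toy_events)[::2]  # drop every other call
        matches, fp, fn = match_calls(calls, toy_events, CFG)
        assert len(matches) + len(fn) == len(toy_events)
        assert len(matches) + len(fp) == len(calls)


class TestScore:
    def test_perfect_match_scores_exactly_one(self):
        matches, _, _ = match_calls([_call()], [_truth()], CFG)
        assert matches[0].score == 1.0

    def test_half_window_offset_scores_point_eight(self):
        matches, _, _ = match_calls([_call(pos=10_800)], [_truth()], CFG)
        assert matches[0].score == pytest.approx(0.8)

    def test_wrong_genotype_costs_point_two(self):
        matches, _, _ = match_calls([_call(gt="het")], [_truth()], CFG)
        assert matches[0].score == pytest.approx(0.8)

    def test_scoring_unmatched_call_raises(self):
        with pytest.raises(ValueError):
            score_call(MatchResult(call=_call(), truth=None), CFG)


class TestMetrics:
    def test_printed_formula_arithmetic(self):
        truth = [_truth(start=5000 + 4000 * i, ident=f"t{i}") for i in range(100)]
        calls = calls_from_truth(truth[:50])
        calls += [_call(pos=1_000_000 + 4000 * i, chrom="chr1") for i in range(50)]
        matches, fp, fn = match_calls(calls, truth, CFG)
        rep = compute_metrics(matches, fp, fn, CFG)
        assert (rep.tp, rep.fp, rep.fn) == (50, 50, 50)
        assert rep.recall == rep.precision == rep.f_score == 0.5
        assert rep.total_score_pct == pytest.approx(100 * (50 - 50) / 100)

    def test_all_perfect_no_fp(self, toy_events):
        rep = benchmark_calls(calls_from_truth(toy_events), toy_events)
        assert rep.recall == rep.precision == rep.f_score == 1.0
        assert rep.total_score_pct == 100.0
        assert rep.perfect_match_pct == 100.0

    def test_zero_calls_degenerate_convention(self, toy_events):
        rep = benchmark_calls([], toy_events)
        assert rep.recall == rep.precision == rep.f_score == 0.0

    def test_total_score_floored_at_zero(self):
        truth = [_truth()]
        calls = [_call(pos=1_000_000), _call(pos=2_000_000), _call(pos=3_000_000)]
        matches, fp, fn = match_calls(calls, truth, CFG)
        rep = compute_metrics(matches, fp, fn, CFG)
        assert rep.total_score_pct == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty truth"):
            compute_metrics([], [], [], CFG)

    def test_per_type_table_flags_unclassifiable_types(self):
        truth = [_truth(sv_type=SVType.CSUB, ident="c1")]
        calls = [_call(sv_type="DEL")]  # callers never emit CSUB
        rep = benchmark_calls(calls, truth)
        row = rep.per_type.set_index("sv_type").loc["CSUB"]
        assert row["recall"] == 1.0
        csub_match = rep.matches[0]
        assert not csub_match.type_correct
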