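"""SV-call benchmarking: filtering, truth matching, scoring and metrics.

Calls are first filtered (FILTER must be PASS — '.' and missing count as
PASS — length >= 50 bp unless undetermined, and a minimum read support of 3,
or 5 at sequencing depths of 30x and above). A filtered call matches a truth
event when it lies within 1600 bp of it and, if the call's length is
determined, the lengths agree within a 35% margin for truth events longer
than 300 bp and exactly for shorter ones (the strictness of the short-SV
rule is configurable). Type and genotype never gate matching. Each matched
call is scored out of 1: 0.4 for position and 0.2 each for length, type and
genotype, the position and length components decaying linearly with the
residual; the total score subtracts one point per false positive and is
expressed as a percentage of the number of truth events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .events import Genotype, SVEvent, SVType

PASS_FILTERS = {"PASS", ".", ""}


@dataclass
class CallRecord:
    """One SV call parsed from a caller VCF."""

    caller: str
    chrom: str
    pos: int
    length: int = 0        # 0 = undetermined (e.g. breakends)
    sv_type: str = "BND"
    genotype: str = "missing"  # het | hom | missing
    support: int | None = None
    filter: str = "PASS"
    id: str = ""
    callers: tuple = ()  # contributing callers (set by the combiner)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"call position {self.pos} < 1")
        if self.length < 0:
            self.length = abs(self.length)


@dataclass
class BenchmarkConfig:
    pos_window: int = 1600
    len_margin: float = 0.35
    len_margin_threshold: int = 300
    min_length: int = 50
    min_support: int = 3
    short_len_margin: float = 0.0
    weights: dict = field(default_factory=lambda: {"pos": 0.4, "len": 0.2,
                                                   "type": 0.2, "gt": 0.2})
    type_equivalences: set = field(default_factory=set)  # {(a, b)} symmetric

    @staticmethod
    def min_support_for_depth(depth: float) -> int:
        return 5 if depth >= 30 else 3

    def types_equal(self, call_type: str, truth_type: str) -> bool:
        if call_type == truth_type:
            return True
        return (call_type, truth_type) in self.type_equivalences \
            or (truth_type, call_type) in self.type_equivalences


@dataclass
class MatchResult:
    call: CallRecord
    truth: SVEvent | None
    delta_pos: int = 0
    delta_len: int = 0
    type_correct: bool = False
    gt_correct: bool = False
    score: float = 0.0


def truth_genotype(ev: SVEvent) -> str:
    return "hom" if ev.genotype is Genotype.HOM else "het"


def calls_from_truth(events: list, caller: str = "truth") -> list:
    """Represent truth events as a (perfect) call set."""
    return [CallRecord(caller=caller, chrom=e.chrom, pos=e.start, length=e.length,
                       sv_type=e.sv_type.value, genotype=truth_genotype(e),
                       support=None, filter="PASS", id=e.id)
            for e in events]


def filter_calls(records: list, config: BenchmarkConfig) -> list:
    """Keep PASS calls of sufficient length and read support."""
    kept = []
    for rec in records:
        if rec.filter not in PASS_FILTERS:
            continue
        if rec.length != 0 and rec.length < config.min_length:
            continue
        if rec.support is not None and rec.support < config.min_support:
            continue
        kept.append(rec)
    return kept


def lengths_compatible(call_length: int, truth_length: int,
                       config: BenchmarkConfig) -> bool:
    """The length gate; an undetermined call length always passes."""
    if call_length == 0:
        return True
    delta = abs(call_length - truth_length)
    if truth_length > config.len_margin_threshold:
        return delta <= config.len_margin * truth_length
    return delta <= config.short_len_margin * truth_length


def score_call(match: MatchResult, config: BenchmarkConfig) -> float:
    """Weighted per-call score out of 1 (position 0.4, rest 0.2 each)."""
    if match.truth is None:
        raise ValueError("cannot score an unmatched call")
    w = config.weights
    pos_part = w["pos"] * max(0.0, 1.0 - abs(match.delta_pos) / config.pos_window)
    if match.call.length == 0:
        len_part = 0.0
    else:
        denom = config.len_margin * match.truth.length
        len_part = w["len"] * max(0.0, 1.0 - abs(match.delta_len) / denom)
    return (pos_part + len_part
            + w["type"] * bool(match.type_correct)
            + w["gt"] * bool(match.gt_correct))


def match_calls(calls: list, truth_set: list, config: BenchmarkConfig
                ) -> tuple[list, list, list]:
    """One-to-one greedy matching by |delta position|, then |delta length|.

    Returns (matches, false-positive calls, false-negative truth events).
    """
    candidates = []
    for ci, call in enumerate(calls):
        for ti, truth in enumerate(truth_set):
            if call.chrom != truth.chrom:
                continue
            dpos = call.pos - truth.start
            if abs(dpos) > config.pos_window:
                continue
            if not lengths_compatible(call.length, truth.length, config):
                continue
            dlen = (call.length - truth.length) if call.length else 0
            candidates.append((abs(dpos), abs(dlen), ci, ti, dpos, dlen))
    candidates.sort()
    used_calls: set = set()
    used_truth: set = set()
    matches: list[MatchResult] = []
    for _, _, ci, ti, dpos, dlen in candidates:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        call, truth = calls[ci], truth_set[ti]
        m = MatchResult(call=call, truth=truth, delta_pos=dpos, delta_len=dlen,
                        type_correct=config.types_equal(call.sv_type,
                                                        truth.sv_type.value),
                        gt_correct=(call.genotype == truth_genotype(truth)))
        m.score = score_call(m, config)
        matches.append(m)
    fp = [c for i, c in enumerate(calls) if i not in used_calls]
    fn = [t for i, t in enumerate(truth_set) if i not in used_truth]
    return matches, fp, fn


@dataclass
class BenchmarkReport:
    recall: float
    precision: float
    f_score: float
    total_score_pct: float
    n_truth: int
    tp: int
    fp: int
    fn: int
    perfect_matches: int
    param_scores: dict
    per_type: pd.DataFrame = field(repr=False, default=None)
    matches: list = field(repr=False, default_factory=list)

    @property
    def perfect_match_pct(self) -> float:
        return 100.0 * self.perfect_matches / self.n_truth if self.n_truth else 0.0

    def to_text(self) -> str:
        lines = [
            f"truth SVs        {self.n_truth}",
            f"TP / FP / FN     {self.tp} / {self.fp} / {self.fn}",
            f"recall           {self.recall:.4f}",
            f"precision        {self.precision:.4f}",
            f"F-score          {self.f_score:.4f}",
            f"total score      {self.total_score_pct:.2f}%",
            f"perfect matches  {self.perfect_matches} ({self.perfect_match_pct:.2f}%)",
            "parameter accuracy: " + ", ".join(
                f"{k}={v:.4f}" for k, v in self.param_scores.items()),
        ]
        if self.per_type is not None and len(self.per_type):
            lines.append("")
            lines.append(self.per_type.to_string())
        return "\n".join(lines)


def compute_metrics(matches: list, fp: list, fn: list,
                    config: BenchmarkConfig) -> BenchmarkReport:
    tp = len(matches)
    n_truth = tp + len(fn)
    if n_truth == 0:
        raise ValueError("empty truth set")
    recall = tp / n_truth
    precision = tp / (tp + len(fp)) if (tp + len(fp)) else 0.0
    f_score = (2 * precision * recall / (precision + recall)
               if precision + recall > 0 else 0.0)
    total = max(0.0, sum(m.score for m in matches) - len(fp))
    total_pct = 100.0 * total / n_truth
    w = config.weights
    perfect = sum(1 for m in matches if m.score >= 1.0 - 1e-12)
    if matches:
        param_scores = {
            "position": float(np.mean([
                max(0.0, 1.0 - abs(m.delta_pos) / config.pos_window) for m in matches])),
            "length": float(np.mean([
                0.0 if m.call.length == 0 else
                max(0.0, 1.0 - abs(m.delta_len) / (config.len_margin * m.truth.length))
                for m in matches])),
            "type": float(np.mean([m.type_correct for m in matches])),
            "genotype": float(np.mean([m.gt_correct for m in matches])),
        }
    else:
        param_scores = {k: 0.0 for k in ("position", "length", "type", "genotype")}

    rows = []
    truth_types = sorted({m.truth.sv_type.value for m in matches}
                         | {t.sv_type.value for t in fn})
    for t in truth_types:
        tp_t = sum(1 for m in matches if m.truth.sv_type.value == t)
        fn_t = sum(1 for e in fn if e.sv_type.value == t)
        called_t = sum(1 for m in matches if m.call.sv_type == t) \
            + sum(1 for c in fp if c.sv_type == t)
        tp_called_t = sum(1 for m in matches if m.call.sv_type == t)
        rows.append({
            "sv_type": t,
            "n_truth": tp_t + fn_t,
            "recall": tp_t / (tp_t + fn_t) if tp_t + fn_t else math.nan,
            "precision": tp_called_t / called_t if called_t else math.nan,
        })
    per_type = pd.DataFrame(rows, columns=["sv_type", "n_truth", "recall", "precision"])
    return BenchmarkReport(recall=recall, precision=precision, f_score=f_score,
                           total_score_pct=total_pct, n_truth=n_truth, tp=tp,
                           fp=len(fp), fn=len(fn), perfect_matches=perfect,
                           param_scores=param_scores, per_type=per_type,
                           matches=matches)


def benchmark_calls(calls: list, truth_set: list,
                    config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Filter, match and score a call set against a truth set."""
    config = config or BenchmarkConfig()
    kept = filter_calls(calls, config)
    matches, fp, fn = match_calls(kept, truth_set, config)
    return compute_metrics(matches, fp, fn, config)


# ---------------------------------------------------------------------------
# Caller VCF I/O
# ---------------------------------------------------------------------------

SUPPORT_INFO_KEYS = ("SUPPORT", "RE", "SR", "SU", "DV")
SUPPORT_FORMAT_KEYS = ("DV", "AD")


def _first_scalar(value):
    if isinstance(value, (tuple, list)):
        value = value[0]
    return value


def read_caller_vcf(path, caller: str = "caller",
                    support_keys=SUPPORT_INFO_KEYS) -> list:
    """Parse a caller VCF into CallRecords, tolerating symbolic ALTs and BNDs."""
    records: list[CallRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                if alt.startswith("<"):
                    svtype = alt.strip("<>")
                elif "[" in alt or "]" in alt:
                    svtype = "BND"
                elif rec.ref and alt and len(rec.ref) > len(alt):
                    svtype = "DEL"
                elif rec.ref and alt and len(alt) > len(rec.ref):
                    svtype = "INS"
                else:
                    svtype = "BND"
            length = 0
            if "SVLEN" in rec.info:
                raw = _first_scalar(rec.info["SVLEN"])
                if raw is not None:
                    length = abs(int(raw))
            elif svtype != "BND" and rec.stop and rec.stop > rec.pos:
                length = rec.stop - rec.pos
            elif rec.ref and alt and not alt.startswith("<") and "[" not in alt:
                length = abs(len(alt) - len(rec.ref))
            support = None
            for key in support_keys:
                if key in rec.info:
                    raw = _first_scalar(rec.info[key])
                    if raw is not None:
                        support = int(raw)
                        break
            genotype = "missing"
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if support is None:
                    for key in SUPPORT_FORMAT_KEYS:
                        if key in sample and sample[key] is not None:
                            raw = _first_scalar(sample[key])
                            if raw is not None:
                                support = int(raw)
                                break
                if gt and None not in gt:
                    n_alt = sum(1 for a in gt if a and a > 0)
                    if n_alt >= 2:
                        genotype = "hom"
                    elif n_alt == 1:
                        genotype = "het"
            filt = list(rec.filter.keys())
            records.append(CallRecord(
                caller=caller, chrom=rec.contig, pos=rec.pos, length=length,
                sv_type=str(svtype), genotype=genotype, support=support,
                filter=filt[0] if filt else ".", id=rec.id or ""))
    return records


def write_calls_vcf(records: list, contigs: dict[str, int], path,
                    source: str = "svsimkit") -> None:
    """Write CallRecords as a sorted VCF 4.2 with symbolic ALT alleles."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line(f"##source={source}")
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of the variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("SUPPORT", 1, "Integer", "Supporting reads")
    header.info.add("CALLERS", ".", "String", "Contributing callers")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")
    order = {name: i for i, name in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, rec in enumerate(sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30),
                                                               r.pos, r.id))):
            if rec.sv_type in ("DEL", "DUP", "INV", "INVDUP") and rec.length:
                stop = min(rec.pos + rec.length - 1, contigs.get(rec.chrom, 1 << 30))
            else:
                stop = rec.pos
            out = vcf.new_record(contig=rec.chrom, start=rec.pos - 1, stop=stop,
                                 alleles=("N", f"<{rec.sv_type}>"),
                                 id=rec.id or f"call{i + 1}",
                                 filter=rec.filter if rec.filter in ("PASS",) else "PASS")
            out.info["SVTYPE"] = rec.sv_type
            if rec.length:
                out.info["SVLEN"] = rec.length
            if rec.support is not None:
                out.info["SUPPORT"] = rec.support
            if rec.callers:
                out.info["CALLERS"] = list(rec.callers)
            gt = {"het": (0, 1), "hom": (1, 1)}.get(rec.genotype, (None,))
            out.samples["SAMPLE"]["GT"] = gt
            vcf.write(out)
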