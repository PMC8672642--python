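"""Rule-based merging of multiple SV callers' VCFs into one consensus set.

Calls from different callers are clustered by position (same tolerance as
the benchmark: 1600 bp window, 35% length margin above 300 bp). A cluster is
emitted when enough distinct callers support it — 2 when combining 2-5
callers, 3 when combining 6 — or when a single-caller rescue rule applies
(by default: homozygous calls from SVIM, heterozygous insertions/deletions
from Sniffles; both categories showed low false-positive rates). Within an
emitted cluster, position and length are taken from the highest-priority
caller present on the position/length ranking (pbsv first), the genotype
from the genotype ranking (cuteSV first), and the SV type from the highest
priority caller reporting a concrete (non-breakend) type. Calls below the
minimum alternative-allele coverage (default 3 reads) are dropped on input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pysam

from .benchmark import BenchmarkConfig, CallRecord, lengths_compatible, \
    read_caller_vcf, write_calls_vcf

logger = logging.getLogger(__name__)

DEFAULT_POSITION_PRIORITY = ("pbsv", "cuteSV", "Sniffles", "SVIM", "NanoVar", "NanoSV")
DEFAULT_GENOTYPE_PRIORITY = ("cuteSV", "pbsv", "Sniffles", "SVIM", "NanoVar", "NanoSV")
DEFAULT_ANCHOR_CALLERS = frozenset({"cuteSV", "Sniffles", "pbsv"})
_UNTYPED = {"BND", "unknown", "", None}


@dataclass
class RescueRule:
    """Admit singleton calls of a low-false-positive category."""

    caller: str
    sv_types: frozenset | None = None   # None = any type
    genotypes: frozenset | None = None  # None = any genotype

    def matches(self, call: CallRecord) -> bool:
        if call.caller.lower() != self.caller.lower():
            return False
        if self.sv_types is not None and call.sv_type not in self.sv_types:
            return False
        if self.genotypes is not None and call.genotype not in self.genotypes:
            return False
        return True


def default_rescue_rules() -> list:
    return [RescueRule("SVIM", None, frozenset({"hom"})),
            RescueRule("Sniffles", frozenset({"INS", "DEL"}), frozenset({"het"}))]


@dataclass
class CombineConfig:
    position_priority: tuple = DEFAULT_POSITION_PRIORITY
    genotype_priority: tuple = DEFAULT_GENOTYPE_PRIORITY
    min_callers: int | None = None  # None: 2 for 2-5 inputs, 3 for 6
    min_alt_coverage: int = 3
    rescue_rules: list = field(default_factory=default_rescue_rules)
    anchor_callers: frozenset = DEFAULT_ANCHOR_CALLERS
    merge_window: int = 1600
    matching: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    def resolve_min_callers(self, n_inputs: int) -> int:
        if self.min_callers is not None:
            return self.min_callers
        return 3 if n_inputs >= 6 else 2

    def _rank(self, priority: tuple, caller: str) -> int:
        lowered = [c.lower() for c in priority]
        return lowered.index(caller.lower()) if caller.lower() in lowered else len(priority)


def load_caller_vcfs(paths_with_labels, config: CombineConfig | None = None) -> list:
    """Read labelled caller VCFs; drops calls below min_alt_coverage."""
    config = config or CombineConfig()
    items = list(paths_with_labels.items()) if isinstance(paths_with_labels, dict) \
        else list(paths_with_labels)
    if len(items) < 2:
        raise ValueError("combining requires at least two caller VCFs")
    labels = [label for label, _ in items]
    if not {l.lower() for l in labels} & {a.lower() for a in config.anchor_callers}:
        warnings.warn("none of the recommended anchor callers "
                      f"({', '.join(sorted(config.anchor_callers))}) among inputs",
                      stacklevel=2)
    calls: list[CallRecord] = []
    for label, path in items:
        for rec in read_caller_vcf(path, caller=label):
            if rec.support is not None and rec.support < config.min_alt_coverage:
                continue
            calls.append(rec)
    return calls


def cluster_calls(calls: list, config: CombineConfig | None = None) -> list:
    """Group same-locus calls; at most one call per caller per group."""
    config = config or CombineConfig()
    groups: list[list[CallRecord]] = []
    anchors: list[CallRecord] = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.caller, c.id)):
        best = None
        for gi in range(len(groups) - 1, -1, -1):
            anchor = anchors[gi]
            if anchor.chrom != call.chrom:
                continue
            dpos = call.pos - anchor.pos
            if abs(dpos) > config.merge_window:
                continue
            ref_len = anchor.length if anchor.length else call.length
            if not lengths_compatible(call.length, ref_len or 1, config.matching) \
                    and ref_len:
                continue
            if best is None or abs(dpos) < best[0]:
                best = (abs(dpos), gi)
        if best is None:
            groups.append([call])
            anchors.append(call)
            continue
        _, gi = best
        same = [m for m in groups[gi] if m.caller == call.caller]
        if same:
            old = same[0]
            if abs(call.pos - anchors[gi].pos) < abs(old.pos - anchors[gi].pos):
                groups[gi].remove(old)
                groups[gi].append(call)
                groups.append([old])  # evicted call stands alone
                anchors.append(old)
            else:
                groups.append([call])
                anchors.append(call)
        else:
            groups[gi].append(call)
    return groups


def resolve_group(group: list, config: CombineConfig,
                  min_callers: int) -> CallRecord | None:
    """Consensus record for one cluster, or None when unsupported."""
    callers = {m.caller for m in group}
    rescued = len(callers) < min_callers and any(
        rule.matches(m) for rule in config.rescue_rules for m in group)
    if len(callers) < min_callers and not rescued:
        return None
    by_pos_rank = sorted(group, key=lambda m: (
        config._rank(config.position_priority, m.caller), m.caller, m.pos))
    lead = by_pos_rank[0]
    typed = [m for m in by_pos_rank if m.sv_type not in _UNTYPED]
    sv_type = typed[0].sv_type if typed else lead.sv_type
    if typed and len({m.sv_type for m in typed}) > 1:
        logger.debug("type conflict at %s:%d resolved to %s by priority",
                     lead.chrom, lead.pos, sv_type)
    by_gt_rank = sorted((m for m in group if m.genotype != "missing"),
                        key=lambda m: (config._rank(config.genotype_priority, m.caller),
                                       m.caller, m.pos))
    genotype = by_gt_rank[0].genotype if by_gt_rank else "missing"
    supports = [m.support for m in group if m.support is not None]
    return replace(lead, sv_type=sv_type, genotype=genotype,
                   support=max(supports) if supports else None,
                   caller="combined", filter="PASS",
                   callers=tuple(sorted(callers)))


def combine(paths_with_labels, config: CombineConfig | None = None,
            out_path=None, no_singletons: bool = False) -> list:
    """Merge caller VCFs into a consensus call list (optionally written as VCF)."""
    config = config or CombineConfig()
    if no_singletons:
        config = replace(config, rescue_rules=[])
    items = list(paths_with_labels.items()) if isinstance(paths_with_labels, dict) \
        else list(paths_with_labels)
    calls = load_caller_vcfs(items, config)
    min_callers = config.resolve_min_callers(len(items))
    merged = combine_calls(calls, config, min_callers)
    if out_path is not None:
        contigs: dict[str, int] = {}
        for _, path in items:
            with pysam.VariantFile(str(path)) as vcf:
                for name, contig in vcf.header.contigs.items():
                    contigs.setdefault(name, contig.length or (1 << 29))
        write_calls_vcf(merged, contigs, out_path, source="svsimkit-combine")
    return merged


def combine_calls(calls: list, config: CombineConfig, min_callers: int) -> list:
    groups = cluster_calls(calls, config)
    merged = [rec for group in groups
              if (rec := resolve_group(group, config, min_callers)) is not None]
    merged.sort(key=lambda r: (r.chrom, r.pos, r.id))
    return merged
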