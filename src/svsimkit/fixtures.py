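"""Synthetic fixtures: toy genomes, pseudo-callers and the round-trip driver.

A pseudo-caller turns a truth set into a caller-style VCF with controlled
error modes — position jitter, multiplicative length noise, dropped events
(false negatives), injected false positives, genotype flips and type
confusion (e.g. insertions reported as duplications, or complex
substitutions reported as deletions, both failure modes real callers show).
Because every distortion is parameterized and seeded, benchmark results on
pseudo-callers have known expectations, which the test-suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_sequence
from .benchmark import BenchmarkConfig, CallRecord, benchmark_calls, truth_genotype
from .combine import CombineConfig, combine_calls
from .errorprofile import ErrorProfile
from .events import Genotype, SVEvent, SVType
from .readsim import ReadSimConfig, simulate_reads
from .svgen import SVSimConfig, apply_svs, generate_random_svs

# per-type mix of the 24,600-SV human truth set used as the study condition
HUMAN_SV_MIX = {SVType.INS: 10469, SVType.DEL: 10031, SVType.DUP: 857,
                SVType.INV: 170, SVType.CSUB: 3073}


def derive_seeds(seed: int, n: int) -> list:
    """Fan a global seed out to per-stage sub-seeds (all below 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def make_toy_genome(n_chroms: int = 1, length: int = 100_000, gc: float = 0.5,
                    seed: int = 0) -> dict[str, str]:
    """Reproducible random genome with the requested GC content."""
    if length < 1000:
        raise ValueError("chromosome length must be at least 1000 bp")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": random_sequence(length, rng, gc=gc)
            for i in range(n_chroms)}


def scaled_sv_counts(n_svs: int, mix: dict | None = None) -> dict:
    """Scale the human per-type SV mix down to ``n_svs`` total events."""
    mix = mix or HUMAN_SV_MIX
    total = sum(mix.values())
    counts = {t: round(n_svs * c / total) for t, c in mix.items()}
    # adjust the largest class so the total is exact
    drift = n_svs - sum(counts.values())
    largest = max(counts, key=counts.get)
    counts[largest] += drift
    return {t: c for t, c in counts.items() if c > 0}


@dataclass
class PseudoCallerSpec:
    """Error model of a synthetic caller applied to a truth set."""

    name: str
    pos_jitter_sd: float = 0.0        # bp, Gaussian
    len_jitter_frac: float = 0.0      # multiplicative Gaussian sd
    fn_rate: float = 0.0              # per-event drop probability
    fp_per_mb: float = 0.0            # injected false positives per Mb
    gt_error_rate: float = 0.0
    type_confusion: dict = field(default_factory=dict)  # type -> (type, prob)
    seed: int = 0

    def validate(self) -> "PseudoCallerSpec":
        for r in (self.fn_rate, self.gt_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        return self


def perturb_truth(truth: list, spec: PseudoCallerSpec, genome) -> list:
    """Emit a caller-style call list for a truth set under the spec's error model.

    ``genome`` is a name -> sequence (or name -> length) mapping; injected
    false positives are placed at least two match windows away from every
    truth event so benchmark FP counts equal the injected count exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = {c: (len(s) if isinstance(s, str) else int(s))
                     for c, s in genome.items()}
    calls: list[CallRecord] = []
    for i, ev in enumerate(truth):
        if rng.random() < spec.fn_rate:
            continue
        pos = ev.start
        if spec.pos_jitter_sd > 0:
            pos = max(1, int(round(pos + rng.normal(0, spec.pos_jitter_sd))))
        length = ev.length
        if spec.len_jitter_frac > 0:
            length = max(1, int(round(length * (1 + rng.normal(0, spec.len_jitter_frac)))))
        sv_type = ev.sv_type.value
        conf = spec.type_confusion.get(sv_type)
        if conf is not None and rng.random() < conf[1]:
            sv_type = conf[0]
        genotype = truth_genotype(ev)
        if spec.gt_error_rate > 0 and rng.random() < spec.gt_error_rate:
            genotype = "hom" if genotype == "het" else "het"
        calls.append(CallRecord(caller=spec.name, chrom=ev.chrom, pos=pos,
                                length=length, sv_type=sv_type, genotype=genotype,
                                support=int(rng.integers(8, 31)),
                                id=f"{spec.name}_{i + 1}"))
    calls.extend(_inject_false_positives(truth, spec, chrom_lengths, rng))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.id))
    return calls


def _inject_false_positives(truth, spec, chrom_lengths, rng,
                            exclusion: int = 3200) -> list:
    genome_size = sum(chrom_lengths.values())
    n_fp = int(round(spec.fp_per_mb * genome_size / 1e6))
    if n_fp == 0:
        return []
    taken = {c: sorted(e.start for e in truth if e.chrom == c) for c in chrom_lengths}
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    fps = []
    attempts = 0
    while len(fps) < n_fp and attempts < 10_000 * n_fp:
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        occupied = taken[chrom]
        j = np.searchsorted(occupied, pos)
        near = [occupied[k] for k in (j - 1, j) if 0 <= k < len(occupied)]
        if any(abs(pos - p) < exclusion for p in near):
            continue
        length = int(round(np.exp(rng.uniform(np.log(50), np.log(5000)))))
        fps.append(CallRecord(
            caller=spec.name, chrom=chrom, pos=pos, length=length,
            sv_type=str(rng.choice(["DEL", "INS", "DUP", "INV"])),
            genotype=str(rng.choice(["het", "hom"])),
            support=int(rng.integers(8, 31)), id=f"{spec.name}_fp{len(fps) + 1}"))
    if len(fps) < n_fp:
        raise RuntimeError("could not place the requested false positives")
    return fps


def identity_spec(name: str = "identity", seed: int = 0) -> PseudoCallerSpec:
    return PseudoCallerSpec(name=name, seed=seed)


def default_pseudo_callers(seeds) -> list:
    """Three plausible caller error models (jitter in bp, FP per Mb)."""
    return [
        PseudoCallerSpec("alpha", pos_jitter_sd=30, len_jitter_frac=0.05,
                         fn_rate=0.10, fp_per_mb=2.0, gt_error_rate=0.05,
                         type_confusion={"CSUB": ("DEL", 1.0)}, seed=seeds[0]),
        PseudoCallerSpec("beta", pos_jitter_sd=80, len_jitter_frac=0.10,
                         fn_rate=0.15, fp_per_mb=5.0, gt_error_rate=0.10,
                         type_confusion={"CSUB": ("DEL", 1.0),
                                         "INS": ("DUP", 0.2)}, seed=seeds[1]),
        PseudoCallerSpec("gamma", pos_jitter_sd=15, len_jitter_frac=0.02,
                         fn_rate=0.20, fp_per_mb=1.0, gt_error_rate=0.02,
                         type_confusion={"CSUB": ("DEL", 1.0)}, seed=seeds[2]),
    ]


@dataclass
class RoundtripReport:
    table: pd.DataFrame
    n_events: int
    total_read_bases: int
    mean_read_identity: float

    def to_text(self) -> str:
        head = (f"events simulated     {self.n_events}\n"
                f"read bases           {self.total_read_bases}\n"
                f"mean read identity   {self.mean_read_identity:.4f}\n")
        return head + "\n" + self.table.to_string(index=False)


def run_roundtrip(seed: int = 0, n_chroms: int = 2, chrom_length: int = 500_000,
                  n_svs: int = 200, coverage: float = 15.0,
                  profile: ErrorProfile | None = None,
                  pseudo_callers: list | None = None,
                  benchmark_config: BenchmarkConfig | None = None,
                  out_dir=None) -> RoundtripReport:
    """simulate SVs -> simulate reads -> pseudo-call -> benchmark -> combine.

    Every stage draws from a sub-seed derived from ``seed``, so reports are
    byte-identical across reruns. The combined call set is benchmarked with
    the same configuration as the individual pseudo-callers.
    """
    seeds = derive_seeds(seed, 8)
    genome = make_toy_genome(n_chroms=n_chroms, length=chrom_length, seed=seeds[0])
    sv_cfg = SVSimConfig(counts_by_type=scaled_sv_counts(n_svs),
                         default_length_range=(50, 5000),
                         telomere_window_bp=min(10_000, chrom_length // 4),
                         seed=seeds[1])
    events = generate_random_svs(sv_cfg, genome)
    applied = apply_svs(genome, events)
    profile = profile or ErrorProfile.synthetic(seed=seeds[2])
    read_cfg = ReadSimConfig(coverage=coverage, median_length=5000,
                             length_range=(1000, 20_000), seed=seeds[3])
    reads = simulate_reads({"hap1": applied["hap1"], "hap2": applied["hap2"]},
                           profile, read_cfg)
    total_bases = sum(r.template_length for r in reads)
    mean_identity = float(np.mean([r.identity for r in reads])) if reads else 1.0

    specs = pseudo_callers if pseudo_callers is not None \
        else default_pseudo_callers(seeds[4:7])
    bench_cfg = benchmark_config or BenchmarkConfig()
    rows = []
    all_calls: list[CallRecord] = []
    for spec in specs:
        calls = perturb_truth(events, spec, genome)
        all_calls.extend(calls)
        rows.append(_report_row(spec.name, benchmark_calls(calls, events, bench_cfg)))
    combine_cfg = CombineConfig(merge_window=bench_cfg.pos_window, matching=bench_cfg)
    merged = combine_calls(all_calls, combine_cfg,
                           combine_cfg.resolve_min_callers(len(specs)))
    rows.append(_report_row("combined", benchmark_calls(merged, events, bench_cfg)))
    table = pd.DataFrame(rows)
    report = RoundtripReport(table=table, n_events=len(events),
                             total_read_bases=total_bases,
                             mean_read_identity=mean_identity)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "roundtrip.tsv", sep="\t", index=False)
        (out_dir / "roundtrip.txt").write_text(report.to_text() + "\n")
    return report


def _report_row(name: str, report) -> dict:
    return {"caller": name, "tp": report.tp, "fp": report.fp, "fn": report.fn,
            "recall": round(report.recall, 4), "precision": round(report.precision, 4),
            "f_score": round(report.f_score, 4),
            "total_score_pct": round(report.total_score_pct, 2),
            "perfect_pct": round(report.perfect_match_pct, 2)}
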