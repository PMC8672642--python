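"""Long-read simulation from haplotype sequences with a 3-mer error profile.

Reads are drawn from the two haplotypes with equal probability (Bernoulli per
read), placed uniformly or following a windowed sequencing-depth profile,
reverse-complemented on a 50/50 strand coin, and corrupted base-by-base with
the profile's context-specific substitution/insertion/deletion process. The
exact edit list of every read is kept as ground truth, so downstream checks
(error-pattern recovery, coverage accounting, perfect calling) need no
aligner.

Read lengths follow a log-normal law parameterized by its median and
truncated to the configured range; the two halves of the distribution are
sampled with equal probability so the empirical median matches the requested
median for any (min, median, max) triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from ._seq import BASES, revcomp
from .errorprofile import AlignmentRecord, ErrorProfile, scale_profile


@dataclass
class DepthWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    depth: float


@dataclass
class DepthProfile:
    windows: list

    def validate(self) -> "DepthProfile":
        by_chrom: dict[str, list[DepthWindow]] = {}
        for w in self.windows:
            if w.depth < 0:
                raise ValueError(f"negative depth in window {w}")
            if w.end < w.start:
                raise ValueError(f"empty window {w}")
            by_chrom.setdefault(w.chrom, []).append(w)
        for chrom, ws in by_chrom.items():
            ws.sort(key=lambda w: w.start)
            for a, b in zip(ws, ws[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping depth windows on {chrom}")
        return self

    @property
    def total_bases(self) -> float:
        return sum(w.depth * (w.end - w.start + 1) for w in self.windows)

    @classmethod
    def from_tsv(cls, path) -> "DepthProfile":
        windows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, start, end, depth = line.split()[:4]
                windows.append(DepthWindow(chrom, int(start), int(end), float(depth)))
        return cls(windows).validate()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tdepth\n")
            for w in self.windows:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.depth:g}\n")


@dataclass
class ReadSimConfig:
    """Coverage, median length, length range and accuracy — plus a seed."""

    coverage: float | None = None
    median_length: int = 2000
    length_range: tuple = (500, 10_000)
    accuracy_override: float | None = None
    depth_profile: DepthProfile | None = None
    circular: bool = False
    seed: int = 0
    quality_cap: int = 60

    def validate(self) -> "ReadSimConfig":
        lo, hi = self.length_range
        if not lo <= self.median_length <= hi:
            raise ValueError("length_range must bracket median_length")
        if (self.coverage is None) == (self.depth_profile is None):
            raise ValueError("supply exactly one of coverage or depth_profile")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        return self


def sample_read_length(config: ReadSimConfig, rng: np.random.Generator) -> int:
    """One draw from the truncated, median-anchored log-normal length law."""
    lo, hi = config.length_range
    med = config.median_length
    if lo == hi:
        return lo
    sigma = max((math.log(hi) - math.log(lo)) / 4.0, 1e-9)
    mu = math.log(med)
    a = ndtr((math.log(lo) - mu) / sigma)
    b = ndtr((math.log(hi) - mu) / sigma)
    u = rng.random()
    if u < 0.5:  # lower half, truncated to [lo, med]
        q = a + 2 * u * (0.5 - a)
    else:        # upper half, truncated to [med, hi]
        q = 0.5 + 2 * (u - 0.5) * (b - 0.5)
    length = int(round(math.exp(mu + sigma * ndtri(min(max(q, 1e-12), 1 - 1e-12)))))
    return min(max(length, lo), hi)


def sample_read_start(template_length: int, read_length: int,
                      rng: np.random.Generator, windows: list | None = None) -> int:
    """1-based start; uniform, or depth-weighted over windows (reads clip at ends)."""
    if windows is None:
        hi = max(template_length - read_length + 1, 1)
        return int(rng.integers(1, hi + 1))
    spans = [(w.start, min(w.end, template_length), w.depth) for w in windows]
    weights = np.array([d * (e - s + 1) for s, e, d in spans if e >= s], dtype=float)
    spans = [(s, e) for s, e, d in spans if e >= s]
    if not len(weights) or weights.sum() <= 0:
        raise ValueError("depth profile has no sampling mass on this template")
    i = rng.choice(len(weights), p=weights / weights.sum())
    s, e = spans[i]
    return int(rng.integers(s, e + 1))


# ---------------------------------------------------------------------------
# Error process
# ---------------------------------------------------------------------------

def corrupt_sequence(template: str, profile: ErrorProfile,
                     rng: np.random.Generator) -> tuple[str, list]:
    """Apply the profile's error process to a template.

    Each template base is one decision point: a single uniform draw selects
    deletion (run length from the deletion-length law; interior bases of the
    run make no decisions of their own) or substitution, mutually exclusive;
    every emitted base then draws an insertion for the gap 3' of it. The
    first/last base, lacking a full 3-mer, use the profile's mean rates.

    Returns the corrupted read and the edit list
    ``[("sub", pos, base) | ("ins", pos, seq) | ("del", pos, run_length)]``
    with 0-based template positions; insertions land after ``pos``.
    """
    n = len(template)
    if n < 3:
        raise ValueError("template must be at least 3 bp")
    codes = np.frombuffer(template.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    codes = lut[codes]
    mean_sub, mean_ins, mean_del = profile.mean_rates
    p_sub = np.full(n, mean_sub)
    p_ins = np.full(n, mean_ins)
    p_del = np.full(n, mean_del)
    valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    ctx = np.where(valid, codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:], 0)
    p_sub[1:-1] = np.where(valid, profile.sub_rate[ctx], mean_sub)
    p_ins[1:-1] = np.where(valid, profile.ins_rate[ctx], mean_ins)
    p_del[1:-1] = np.where(valid, profile.del_rate[ctx], mean_del)

    u = rng.random(n)
    del_cand = u < p_del
    sub_cand = (~del_cand) & (u < p_del + p_sub)
    ins_cand = rng.random(n) < p_ins

    # resolve deletion runs left to right; candidates inside a run are void
    del_pos = np.flatnonzero(del_cand)
    dlen_dist = profile.del_length_dist
    draws = (rng.choice(len(dlen_dist), size=len(del_pos), p=dlen_dist) + 1
             if len(del_pos) else np.empty(0, dtype=int))
    deleted = np.zeros(n, dtype=bool)
    dels = []
    run_end = -1
    for pos, length in zip(del_pos, draws):
        if pos <= run_end:
            continue
        length = int(min(length, n - pos))
        deleted[pos:pos + length] = True
        dels.append((int(pos), length))
        run_end = pos + length - 1

    sub_pos = np.flatnonzero(sub_cand & ~deleted)
    ins_pos = np.flatnonzero(ins_cand & ~deleted)

    # substitution targets per context (uniform over alternatives at the edges)
    sub_bases = []
    if len(sub_pos):
        r = rng.random(len(sub_pos))
        for pos, rv in zip(sub_pos, r):
            if 1 <= pos <= n - 2 and valid[pos - 1]:
                probs = profile.sub_targets[ctx[pos - 1]]
            else:
                probs = np.full(4, 1 / 3)
                if codes[pos] >= 0:
                    probs[codes[pos]] = 0.0
                probs = probs / probs.sum()
            target = int(np.searchsorted(np.cumsum(probs), rv, side="right"))
            sub_bases.append(BASES[min(target, 3)])

    ilen_dist = profile.ins_length_dist
    ins_lens = (rng.choice(len(ilen_dist), size=len(ins_pos), p=ilen_dist) + 1
                if len(ins_pos) else np.empty(0, dtype=int))
    total_ins = int(ins_lens.sum()) if len(ins_lens) else 0
    ins_codes = rng.integers(0, 4, total_ins) if total_ins else np.empty(0, dtype=int)
    ins_seqs = []
    off = 0
    for L in ins_lens:
        ins_seqs.append("".join(BASES[c] for c in ins_codes[off:off + int(L)]))
        off += int(L)

    ops = ([("del", p, L) for p, L in dels]
           + [("sub", int(p), b) for p, b in zip(sub_pos, sub_bases)]
           + [("ins", int(p), s) for p, s in zip(ins_pos, ins_seqs)])
    ops.sort(key=lambda o: (o[1], 0 if o[0] != "ins" else 1))

    parts = []
    cursor = 0
    for op, pos, payload in ops:
        if op == "del":
            parts.append(template[cursor:pos])
            cursor = pos + payload
        elif op == "sub":
            parts.append(template[cursor:pos])
            parts.append(payload)
            cursor = pos + 1
        else:  # ins (after pos)
            if cursor <= pos:
                parts.append(template[cursor:pos + 1])
                cursor = pos + 1
            parts.append(payload)
    parts.append(template[cursor:])
    return "".join(parts), ops


def ops_to_cigar(ops: list, template_len: int) -> list:
    """Edit list -> CIGAR tuples (M/I/D) over the template (substitutions are M)."""
    cigar: list = []

    def add(op, length):
        if length <= 0:
            return
        # only M runs merge: back-to-back D ops are distinct deletion events
        # (independent decision points) and must stay distinct for training
        if op == "M" and cigar and cigar[-1][0] == "M":
            cigar[-1] = ("M", cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    cursor = 0
    for op, pos, payload in ops:
        if op == "del":
            add("M", pos - cursor)
            add("D", payload)
            cursor = pos + payload
        elif op == "ins":
            add("M", pos + 1 - cursor)
            add("I", len(payload))
            cursor = pos + 1
    add("M", template_len - cursor)
    return cigar


def edit_counts(ops: list) -> tuple[int, int, int]:
    """(substituted bases, inserted bases, deleted bases) of an edit list."""
    n_sub = sum(1 for o in ops if o[0] == "sub")
    n_ins = sum(len(o[2]) for o in ops if o[0] == "ins")
    n_del = sum(o[2] for o in ops if o[0] == "del")
    return n_sub, n_ins, n_del


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    read_id: str
    haplotype: str
    chrom: str
    start: int          # 1-based template start on the haplotype sequence
    end: int            # inclusive template end
    strand: str         # "+" or "-"
    sequence: str
    ops: list = field(repr=False, default_factory=list)
    template_length: int = 0

    @property
    def identity(self) -> float:
        n_sub, n_ins, n_del = edit_counts(self.ops)
        return 1.0 - (n_sub + n_ins + n_del) / max(self.template_length, 1)

    def to_alignment(self) -> AlignmentRecord:
        """Exact truth alignment in reference orientation (for profile training)."""
        cigar = ops_to_cigar(self.ops, self.template_length)
        if self.strand == "+":
            return AlignmentRecord(chrom=self.chrom, ref_start=self.start - 1,
                                   cigar=cigar, query=self.sequence, is_reverse=False)
        return AlignmentRecord(chrom=self.chrom, ref_start=self.start - 1,
                               cigar=list(reversed(cigar)),
                               query=revcomp(self.sequence), is_reverse=True)


def _normalize_haplotypes(haplotypes) -> dict[str, dict[str, str]]:
    if haplotypes and isinstance(next(iter(haplotypes.values())), str):
        return {"hap1": haplotypes}
    return dict(haplotypes)


def simulate_reads(haplotypes, profile: ErrorProfile, config: ReadSimConfig,
                   rng: np.random.Generator | None = None) -> list[SimulatedRead]:
    """Simulate reads to the requested coverage; deterministic for a fixed seed.

    ``haplotypes`` maps haplotype label -> {chrom: sequence} (a plain
    {chrom: sequence} mapping is treated as a single haplotype).
    """
    config.validate()
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.accuracy_override is not None:
        profile = scale_profile(profile, config.accuracy_override)
    haps = _normalize_haplotypes(haplotypes)
    labels = list(haps)
    sizes = {lab: sum(len(s) for s in seqs.values()) for lab, seqs in haps.items()}
    mean_size = sum(sizes.values()) / len(sizes)
    if config.depth_profile is not None:
        config.depth_profile.validate()
        target = config.depth_profile.total_bases
        windows_by_chrom: dict[str, list] = {}
        for w in config.depth_profile.windows:
            if w.depth > 0:
                windows_by_chrom.setdefault(w.chrom, []).append(w)
        chrom_mass = {c: sum(w.depth * (w.end - w.start + 1) for w in ws)
                      for c, ws in windows_by_chrom.items()}
    else:
        target = config.coverage * mean_size
        windows_by_chrom = None

    reads: list[SimulatedRead] = []
    total = 0
    i = 0
    while total < target:
        label = labels[int(rng.integers(0, len(labels)))] if len(labels) > 1 else labels[0]
        seqs = haps[label]
        chroms = list(seqs)
        if windows_by_chrom is None:
            lens = np.array([len(seqs[c]) for c in chroms], dtype=float)
            chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        else:
            usable = [c for c in chroms if c in chrom_mass]
            mass = np.array([chrom_mass[c] for c in usable], dtype=float)
            chrom = usable[int(rng.choice(len(usable), p=mass / mass.sum()))]
        seq = seqs[chrom]
        length = min(sample_read_length(config, rng), len(seq))
        start = sample_read_start(len(seq), length, rng,
                                  None if windows_by_chrom is None
                                  else windows_by_chrom.get(chrom))
        if config.circular and start + length - 1 > len(seq):
            template = seq[start - 1:] + seq[:start - 1 + length - len(seq)]
            end = start + length - 1  # wraps past the origin
        else:
            template = seq[start - 1:start - 1 + length]
            end = start + len(template) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        read_seq, ops = corrupt_sequence(template, profile, rng)
        i += 1
        reads.append(SimulatedRead(read_id=f"read{i}", haplotype=label, chrom=chrom,
                                   start=start, end=end, strand=strand,
                                   sequence=read_seq, ops=ops,
                                   template_length=len(template)))
        total += len(template)
    return reads


def write_fastq(reads: list, path, profile: ErrorProfile | None = None,
                quality_cap: int = 60) -> None:
    """FASTQ with a constant quality derived from the profile accuracy."""
    if profile is not None and profile.overall_accuracy < 1:
        q = min(int(round(-10 * math.log10(1 - profile.overall_accuracy))), quality_cap)
    else:
        q = quality_cap
    qchar = chr(q + 33)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qchar * len(read.sequence)}\n")


def write_truth_tsv(reads: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\thap\tchrom\tstart\tend\tstrand\tn_sub\tn_ins\tn_del\n")
        for r in reads:
            n_sub, n_ins, n_del = edit_counts(r.ops)
            fh.write(f"{r.read_id}\t{r.haplotype}\t{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.strand}\t{n_sub}\t{n_ins}\t{n_del}\n")
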