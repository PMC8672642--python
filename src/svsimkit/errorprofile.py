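"""Context-specific sequencing-error profiles.

A profile stores, for each of the 64 possible 3-mer contexts, the
substitution, insertion and deletion rate of the *middle* base, a
substitution-target distribution, plus genome-wide insertion- and
deletion-length distributions. Rates are defined per "decision point": every
reference base that is not interior to a deletion run carries one
substitution-or-deletion decision (the two are mutually exclusive, hence the
``sub + del <= 1`` invariant), and every base actually emitted carries an
independent insertion decision for the gap 3' of it. The trainer below
estimates exactly these quantities from alignments, so simulating from a
profile and retraining recovers it without bias.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import encode_bases

CONTEXTS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
N_CONTEXTS = 64
DEFAULT_L_MAX = 100


def context_code(kmer: str) -> int:
    codes = encode_bases(kmer)
    if codes.min() < 0:
        raise ValueError(f"invalid 3-mer {kmer!r}")
    return int(codes[0] * 16 + codes[1] * 4 + codes[2])


def _middle_base(code: int) -> int:
    return (code >> 2) & 3


def _uniform_targets() -> np.ndarray:
    t = np.full((N_CONTEXTS, 4), 1 / 3)
    for c in range(N_CONTEXTS):
        t[c, _middle_base(c)] = 0.0
    return t


class ProfileError(ValueError):
    """Raised on invalid profiles or unreachable scaling targets."""


@dataclass
class ErrorProfile:
    name: str
    sub_rate: np.ndarray   # (64,)
    ins_rate: np.ndarray   # (64,)
    del_rate: np.ndarray   # (64,)
    sub_targets: np.ndarray = field(default_factory=_uniform_targets)  # (64, 4)
    ins_length_dist: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    del_length_dist: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        for attr in ("sub_rate", "ins_rate", "del_rate", "sub_targets",
                     "ins_length_dist", "del_length_dist"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))

    # -- derived quantities -------------------------------------------------
    @property
    def mean_ins_length(self) -> float:
        return float(np.arange(1, len(self.ins_length_dist) + 1) @ self.ins_length_dist)

    @property
    def mean_del_length(self) -> float:
        return float(np.arange(1, len(self.del_length_dist) + 1) @ self.del_length_dist)

    @property
    def expected_error_per_base(self) -> float:
        """Expected erroneous bases per template base, uniform over contexts."""
        return float(np.mean(self.sub_rate
                             + self.ins_rate * self.mean_ins_length
                             + self.del_rate * self.mean_del_length))

    @property
    def overall_accuracy(self) -> float:
        return 1.0 - self.expected_error_per_base

    @property
    def mean_rates(self) -> tuple[float, float, float]:
        return (float(self.sub_rate.mean()), float(self.ins_rate.mean()),
                float(self.del_rate.mean()))

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ErrorProfile":
        for label, r in (("sub", self.sub_rate), ("ins", self.ins_rate),
                         ("del", self.del_rate)):
            if r.shape != (N_CONTEXTS,):
                raise ProfileError(f"{label}_rate must have 64 entries")
            if (r < 0).any() or (r > 1).any():
                raise ProfileError(f"{label}_rate outside [0, 1]")
        if (self.sub_rate + self.del_rate > 1 + 1e-12).any():
            raise ProfileError("sub_rate + del_rate exceeds 1 for some context")
        for label, d in (("sub_targets", self.sub_targets),):
            if d.shape != (N_CONTEXTS, 4) or (d < 0).any():
                raise ProfileError("sub_targets must be a 64x4 non-negative matrix")
            if not np.allclose(d.sum(axis=1), 1.0, atol=1e-9):
                raise ProfileError("sub_targets rows must sum to 1")
            if any(d[c, _middle_base(c)] > 1e-12 for c in range(N_CONTEXTS)
                   if self.sub_rate[c] > 0):
                raise ProfileError("sub_targets may not keep the reference base")
        for label, d in (("ins_length_dist", self.ins_length_dist),
                         ("del_length_dist", self.del_length_dist)):
            if (d < 0).any() or abs(d.sum() - 1.0) > 1e-9:
                raise ProfileError(f"{label} must be a distribution summing to 1")
        return self

    # -- constructors -------------------------------------------------------
    @classmethod
    def uniform(cls, sub: float, ins: float, dele: float,
                ins_length_dist=None, del_length_dist=None,
                name: str = "uniform") -> "ErrorProfile":
        return cls(name=name,
                   sub_rate=np.full(N_CONTEXTS, sub),
                   ins_rate=np.full(N_CONTEXTS, ins),
                   del_rate=np.full(N_CONTEXTS, dele),
                   ins_length_dist=np.array(ins_length_dist if ins_length_dist is not None else [1.0]),
                   del_length_dist=np.array(del_length_dist if del_length_dist is not None else [1.0])).validate()

    @classmethod
    def synthetic(cls, seed: int = 0, mean_sub: float = 0.02, mean_ins: float = 0.01,
                  mean_del: float = 0.015, spread: float = 0.5,
                  name: str = "synthetic") -> "ErrorProfile":
        """A context-varying profile for testing: rates jitter around the means."""
        rng = np.random.default_rng(seed)
        def draw(mean):
            return np.clip(mean * (1 + spread * (rng.random(N_CONTEXTS) * 2 - 1)), 1e-6, 0.45)
        ins_d = np.array([0.6, 0.3, 0.1])
        del_d = np.array([0.55, 0.3, 0.15])
        return cls(name=name, sub_rate=draw(mean_sub), ins_rate=draw(mean_ins),
                   del_rate=draw(mean_del), ins_length_dist=ins_d,
                   del_length_dist=del_d).validate()


# ---------------------------------------------------------------------------
# Accuracy rescaling
# ---------------------------------------------------------------------------

def _scaled_rates(profile: ErrorProfile, factor: float):
    sub = profile.sub_rate * factor
    dele = profile.del_rate * factor
    ins = np.clip(profile.ins_rate * factor, 0.0, 1.0)
    total = sub + dele
    over = total > 1.0
    clipped = bool(over.any() or (profile.ins_rate * factor > 1.0).any())
    if over.any():
        shrink = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
        sub = sub * shrink
        dele = dele * shrink
    return sub, ins, dele, clipped


def scale_profile(profile: ErrorProfile, target_accuracy: float) -> ErrorProfile:
    """Rescale all context rates by one factor to hit a target overall accuracy.

    Relative differences between contexts are preserved; where the factor
    would push ``sub + del`` past 1 (or an insertion rate past 1) the context
    saturates at the boundary with a warning. Raises if the target is below
    the accuracy achievable at full saturation.
    """
    if not 0 < target_accuracy <= 1:
        raise ProfileError("target accuracy must be in (0, 1]")
    profile.validate()

    def accuracy_at(f: float) -> float:
        sub, ins, dele, _ = _scaled_rates(profile, f)
        trial = replace(profile, sub_rate=sub, ins_rate=ins, del_rate=dele)
        return trial.overall_accuracy

    if target_accuracy == 1.0:
        z = np.zeros(N_CONTEXTS)
        return replace(profile, sub_rate=z, ins_rate=z.copy(), del_rate=z.copy())
    current_err = profile.expected_error_per_base
    if current_err <= 0:
        raise ProfileError("cannot scale an error-free profile to accuracy < 1")
    hi = (1 - target_accuracy) / current_err
    for _ in range(200):  # grow past any clipping until the target is bracketed
        if accuracy_at(hi) <= target_accuracy:
            break
        new_hi = hi * 2
        if accuracy_at(new_hi) >= accuracy_at(hi) - 1e-15:  # saturated
            raise ProfileError(
                f"target accuracy {target_accuracy} unreachable: error saturates "
                f"at accuracy {accuracy_at(hi):.6f}")
        hi = new_hi
    else:  # pragma: no cover
        raise ProfileError("target accuracy unreachable")
    lo = 0.0
    for _ in range(100):
        mid = (lo + hi) / 2
        if accuracy_at(mid) > target_accuracy:
            lo = mid
        else:
            hi = mid
    factor = hi
    sub, ins, dele, clipped = _scaled_rates(profile, factor)
    if clipped:
        warnings.warn("accuracy scaling clipped one or more contexts at the "
                      "sub+del <= 1 boundary", stacklevel=2)
    out = replace(profile, sub_rate=sub, ins_rate=ins, del_rate=dele,
                  name=f"{profile.name}@{target_accuracy:g}")
    if abs(out.overall_accuracy - target_accuracy) > 1e-6:
        raise ProfileError("accuracy scaling failed to converge")
    return out.validate()


# ---------------------------------------------------------------------------
# Training from alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """A CIGAR-resolved read-to-reference alignment in reference orientation.

    ``is_reverse`` marks reads sequenced from the minus strand; their errors
    arose in read orientation, so the trainer tabulates them against
    reverse-complement contexts.
    """

    chrom: str
    ref_start: int          # 0-based
    cigar: list             # [(op, length)] with op in M/=/X/I/D/S/H
    query: str              # read bases, reference orientation
    is_reverse: bool = False


class _Tabulation:
    def __init__(self, lmax: int):
        self.lmax = lmax
        self.decision_den = np.zeros(N_CONTEXTS)
        self.aligned_den = np.zeros(N_CONTEXTS)
        self.sub_cnt = np.zeros((N_CONTEXTS, 4))
        self.ins_cnt = np.zeros(N_CONTEXTS)
        self.del_cnt = np.zeros(N_CONTEXTS)
        self.ins_len = np.zeros(lmax)
        self.del_len = np.zeros(lmax)
        self.long_indels = 0


def _ref_arrays(reference: dict[str, str]):
    """Per-chromosome base codes plus forward and reverse-complement contexts."""
    arrays = {}
    for chrom, seq in reference.items():
        codes = encode_bases(seq)
        n = len(codes)
        ctx = np.full(n, -1, dtype=np.int64)
        ctx_rc = np.full(n, -1, dtype=np.int64)
        if n >= 3:
            valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
            ctx[1:-1] = np.where(valid, codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:], -1)
            ctx_rc[1:-1] = np.where(
                valid,
                (3 - codes[2:]) * 16 + (3 - codes[1:-1]) * 4 + (3 - codes[:-2]), -1)
        arrays[chrom] = (codes, ctx, ctx_rc)
    return arrays


def _tabulate_record(rec: AlignmentRecord, ref_codes, ref_ctx, ref_ctx_rc,
                     tab: _Tabulation) -> int:
    qcodes = encode_bases(rec.query)
    ref_len = len(ref_codes)
    ctx_arr = ref_ctx_rc if rec.is_reverse else ref_ctx
    # first/last aligned reference positions are skipped (no full read context)
    total_ref = sum(length for op, length in rec.cigar if op in "M=XD")
    if total_ref == 0:
        return 0
    first_ref, last_ref = rec.ref_start, rec.ref_start + total_ref - 1
    skip = (first_ref, last_ref)
    rp, qp = rec.ref_start, 0
    aligned = 0

    def count_indel(ctx_code: int, length: int, cnt, len_hist) -> None:
        cnt[ctx_code] += 1
        if length > tab.lmax:
            tab.long_indels += 1
        len_hist[min(length, tab.lmax) - 1] += 1

    for op, length in rec.cigar:
        if op in "M=X":
            r = np.arange(rp, rp + length)
            q = qcodes[qp:qp + length]
            mask = (ctx_arr[r] >= 0) & (r != first_ref) & (r != last_ref) & (q >= 0)
            ctx = ctx_arr[r[mask]]
            np.add.at(tab.decision_den, ctx, 1)
            np.add.at(tab.aligned_den, ctx, 1)
            mism = mask & (q != ref_codes[r])
            if mism.any():
                target = q[mism] if not rec.is_reverse else 3 - q[mism]
                np.add.at(tab.sub_cnt, (ctx_arr[r[mism]], target), 1)
            aligned += int(mask.sum())
            rp += length
            qp += length
        elif op == "I":
            # anchor on the base 5' of the insertion in *read* orientation
            anchor = rp if rec.is_reverse else rp - 1
            if rec.ref_start < rp and 0 <= anchor < ref_len \
                    and ctx_arr[anchor] >= 0 and anchor not in skip:
                count_indel(ctx_arr[anchor], length, tab.ins_cnt, tab.ins_len)
            qp += length
        elif op == "D":
            # the run start in read orientation is the decision point
            head = rp + length - 1 if rec.is_reverse else rp
            if 0 <= head < ref_len and ctx_arr[head] >= 0 and head not in skip:
                tab.decision_den[ctx_arr[head]] += 1
                count_indel(ctx_arr[head], length, tab.del_cnt, tab.del_len)
            rp += length  # interior deleted bases are not decision points
        elif op == "S":
            qp += length
        elif op == "H":
            pass
        else:
            raise ProfileError(f"unsupported CIGAR op {op!r}")
    return aligned


def train_profile(alignments, reference: dict[str, str], lmax: int = DEFAULT_L_MAX,
                  name: str = "trained") -> ErrorProfile:
    """Estimate a 3-mer error profile from CIGAR-resolved alignments.

    ``alignments`` is an iterable of :class:`AlignmentRecord`. Contexts never
    observed receive the genome-wide mean rate; indels longer than ``lmax``
    are counted at ``lmax`` with a warning (at that size they are structural
    variants, not sequencing errors).

    The returned profile carries the per-context observation counts used as
    rate denominators in ``training_decision_counts`` (substitution/deletion
    decisions) and ``training_aligned_counts`` (insertion decisions), so
    callers can attach binomial uncertainties to the estimated rates.
    """
    arrays = _ref_arrays(reference)
    tab = _Tabulation(lmax)
    total_aligned = 0
    for rec in alignments:
        if rec.chrom not in arrays:
            raise ProfileError(f"alignment references unknown contig {rec.chrom!r}")
        codes, ctx, ctx_rc = arrays[rec.chrom]
        total_aligned += _tabulate_record(rec, codes, ctx, ctx_rc, tab)
    if total_aligned == 0:
        raise ProfileError("no aligned bases to train from")
    if tab.long_indels:
        warnings.warn(f"{tab.long_indels} indels longer than {lmax} bp clipped "
                      "during training (likely SVs, not errors)", stacklevel=2)

    def rate(cnt, den):
        mean = cnt.sum() / max(den.sum(), 1.0)
        out = np.full(N_CONTEXTS, mean)
        seen = den > 0
        out[seen] = cnt[seen] / den[seen]
        return out

    sub_rate = rate(tab.sub_cnt.sum(axis=1), tab.decision_den)
    del_rate = rate(tab.del_cnt, tab.decision_den)
    ins_rate = rate(tab.ins_cnt, tab.aligned_den)
    targets = _uniform_targets()
    row_tot = tab.sub_cnt.sum(axis=1)
    for c in np.flatnonzero(row_tot > 0):
        targets[c] = tab.sub_cnt[c] / row_tot[c]

    def length_dist(cnt):
        if cnt.sum() == 0:
            return np.array([1.0])
        d = cnt / cnt.sum()
        return d[:np.flatnonzero(d)[-1] + 1]

    profile = ErrorProfile(name=name, sub_rate=sub_rate, ins_rate=ins_rate,
                           del_rate=del_rate, sub_targets=targets,
                           ins_length_dist=length_dist(tab.ins_len),
                           del_length_dist=length_dist(tab.del_len)).validate()
    profile.training_decision_counts = tab.decision_den.copy()
    profile.training_aligned_counts = tab.aligned_den.copy()
    profile.training_indel_counts = (tab.ins_len.copy(), tab.del_len.copy())
    return profile


_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 6: "P", 7: "=", 8: "X"}


def train_profile_from_sam(sam_path, reference: dict[str, str],
                           lmax: int = DEFAULT_L_MAX, name: str = "trained") -> ErrorProfile:
    """Train from a SAM/BAM file (primary alignments only)."""
    import pysam

    def records():
        with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                cigar = [(_PYSAM_OPS[op], ln) for op, ln in read.cigartuples]
                yield AlignmentRecord(chrom=read.reference_name,
                                      ref_start=read.reference_start,
                                      cigar=cigar, query=read.query_sequence,
                                      is_reverse=read.is_reverse)

    return train_profile(records(), reference, lmax=lmax, name=name)


def align_reads(reads, reference: dict[str, str]):
    """Infix-align raw reads (both orientations) with edlib; yields records.

    Intended for toy-scale profile training straight from FASTA/FASTQ reads
    when no aligner output is available.
    """
    import re

    import edlib

    from ._seq import revcomp

    cigar_re = re.compile(r"(\d+)([=XIDM])")
    for read in reads:
        best = None
        for is_reverse, seq in ((False, read), (True, revcomp(read))):
            for chrom, ref in reference.items():
                aln = edlib.align(seq, ref, task="path", mode="HW")
                if best is None or aln["editDistance"] < best[0]:
                    best = (aln["editDistance"], chrom, aln, seq, is_reverse)
        _, chrom, aln, seq, is_reverse = best
        start = aln["locations"][0][0]
        cigar = [(op, int(n)) for n, op in cigar_re.findall(aln["cigar"])]
        yield AlignmentRecord(chrom=chrom, ref_start=start, cigar=cigar,
                              query=seq, is_reverse=is_reverse)


# ---------------------------------------------------------------------------
# Serialization: plain-text sectioned format
# ---------------------------------------------------------------------------

def save_profile(profile: ErrorProfile, path) -> None:
    profile.validate()
    with open(path, "w") as fh:
        fh.write("[meta]\n")
        fh.write(f"name = {profile.name}\n")
        fh.write(f"accuracy = {profile.overall_accuracy:.9f}\n")
        fh.write("[contexts]\n")
        fh.write("# kmer sub ins del tA tC tG tT\n")
        for c, kmer in enumerate(CONTEXTS):
            t = profile.sub_targets[c]
            fh.write(f"{kmer}\t{profile.sub_rate[c]:.9g}\t{profile.ins_rate[c]:.9g}\t"
                     f"{profile.del_rate[c]:.9g}\t"
                     + "\t".join(f"{x:.9g}" for x in t) + "\n")
        for section, dist in (("ins_lengths", profile.ins_length_dist),
                              ("del_lengths", profile.del_length_dist)):
            fh.write(f"[{section}]\n")
            for i, p in enumerate(dist, 1):
                if p > 0:
                    fh.write(f"{i}\t{p:.12g}\n")


def load_profile(path) -> ErrorProfile:
    name = "profile"
    rows: dict[str, list[float]] = {}
    lengths: dict[str, dict[int, float]] = {"ins_lengths": {}, "del_lengths": {}}
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                if section not in ("meta", "contexts", "ins_lengths", "del_lengths"):
                    raise ProfileError(f"unknown section [{section}]")
                continue
            if section == "meta":
                key, _, value = line.partition("=")
                if key.strip() == "name":
                    name = value.strip()
            elif section == "contexts":
                parts = line.split()
                if len(parts) != 8:
                    raise ProfileError(f"malformed context line: {line!r}")
                rows[parts[0]] = [float(x) for x in parts[1:]]
            elif section in lengths:
                l, p = line.split()
                lengths[section][int(l)] = float(p)
            else:
                raise ProfileError("data before any section header")
    missing = [k for k in CONTEXTS if k not in rows]
    if missing:
        raise ProfileError(f"profile file missing context(s): {', '.join(missing[:5])}")
    sub = np.array([rows[k][0] for k in CONTEXTS])
    ins = np.array([rows[k][1] for k in CONTEXTS])
    dele = np.array([rows[k][2] for k in CONTEXTS])
    targets = np.array([rows[k][3:7] for k in CONTEXTS])
    for c in range(N_CONTEXTS):
        if targets[c].sum() == 0:
            targets[c] = _uniform_targets()[c]

    def dist(d):
        if not d:
            return np.array([1.0])
        arr = np.zeros(max(d))
        for l, p in d.items():
            arr[l - 1] = p
        return arr

    return ErrorProfile(name=name, sub_rate=sub, ins_rate=ins, del_rate=dele,
                        sub_targets=targets,
                        ins_length_dist=dist(lengths["ins_lengths"]),
                        del_length_dist=dist(lengths["del_lengths"])).validate()
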