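"""Structural-variant event model.

An :class:`SVEvent` describes one germline structural variant (>= 50 bp by
convention) on a diploid genome: deletions (DEL), insertions (INS), tandem
duplications (DUP), inverted duplications (INVDUP), inversions (INV),
reciprocal translocations (TRA) and complex substitutions (CSUB, a reference
region deleted and replaced by sequence from elsewhere in the genome).
Coordinates are 1-based inclusive on the unmodified reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

MIN_SV_LENGTH = 50


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INVDUP = "INVDUP"
    INV = "INV"
    TRA = "TRA"
    CSUB = "CSUB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(str, Enum):
    HET_H1 = "HET_H1"  # variant on haplotype 1 only
    HET_H2 = "HET_H2"  # variant on haplotype 2 only
    HOM = "HOM"        # variant on both haplotypes

    @property
    def is_het(self) -> bool:
        return self is not Genotype.HOM

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SVValidationError(ValueError):
    """Raised when an event violates the SV model invariants."""


@dataclass
class SVEvent:
    """One structural variant on the reference.

    ``start`` is 1-based inclusive; ``ref_span`` is the number of reference
    bases the event consumes (0 for pure insertions, which occur *after*
    ``start``); ``length`` is the size of the variant. For TRA,
    ``partner_chrom``/``partner_start`` locate the reciprocal junction and
    ``ref_span`` is 0 (a translocation moves sequence without net gain/loss).
    """

    id: str
    chrom: str
    start: int
    sv_type: SVType
    length: int
    ref_span: int = -1  # filled by __post_init__ for types where it is implied
    inserted_seq: str = ""
    copies: int = 1
    genotype: Genotype = Genotype.HOM
    partner_chrom: str | None = None
    partner_start: int | None = None

    def __post_init__(self) -> None:
        self.sv_type = SVType(self.sv_type)
        self.genotype = Genotype(self.genotype)
        if self.ref_span < 0:
            if self.sv_type in (SVType.INS, SVType.TRA):
                self.ref_span = 0
            else:
                self.ref_span = self.length

    @property
    def end(self) -> int:
        """Last reference base consumed (== start - 1 for pure insertions)."""
        return self.start + self.ref_span - 1

    @property
    def length_delta(self) -> int:
        """Signed haplotype-length change caused by applying this event."""
        t = self.sv_type
        if t is SVType.INS:
            return self.length
        if t is SVType.DEL:
            return -self.ref_span
        if t in (SVType.DUP, SVType.INVDUP):
            return self.length * self.copies
        if t is SVType.CSUB:
            return self.length - self.ref_span
        return 0  # INV, TRA (genome-total for TRA)

    def validate(self, chrom_lengths: dict[str, int] | None = None,
                 min_length: int = MIN_SV_LENGTH) -> "SVEvent":
        t = self.sv_type
        if self.length < min_length:
            raise SVValidationError(
                f"{self.id}: SV length {self.length} below minimum {min_length}")
        if self.start < 1:
            raise SVValidationError(f"{self.id}: start {self.start} < 1")
        if t in (SVType.DEL, SVType.INV) and self.ref_span != self.length:
            raise SVValidationError(f"{self.id}: {t} requires ref_span == length")
        if t is SVType.INS:
            if self.ref_span != 0:
                raise SVValidationError(f"{self.id}: INS must have ref_span 0")
            if len(self.inserted_seq) != self.length:
                raise SVValidationError(
                    f"{self.id}: INS requires inserted sequence of length {self.length}")
        if t is SVType.CSUB:
            if self.ref_span < min_length:
                raise SVValidationError(
                    f"{self.id}: CSUB replaced span {self.ref_span} below {min_length}")
            if len(self.inserted_seq) != self.length:
                raise SVValidationError(
                    f"{self.id}: CSUB requires replacement sequence of length {self.length}")
        if t in (SVType.DUP, SVType.INVDUP):
            if self.ref_span != self.length:
                raise SVValidationError(f"{self.id}: {t} unit requires ref_span == length")
            if self.copies < 1:
                raise SVValidationError(f"{self.id}: {t} requires copies >= 1")
        if t is SVType.TRA and (self.partner_chrom is None or self.partner_start is None):
            raise SVValidationError(f"{self.id}: TRA requires a partner locus")
        if chrom_lengths is not None:
            if self.chrom not in chrom_lengths:
                raise SVValidationError(f"{self.id}: unknown chromosome {self.chrom!r}")
            if self.end > chrom_lengths[self.chrom] or self.start > chrom_lengths[self.chrom]:
                raise SVValidationError(
                    f"{self.id}: interval {self.start}-{self.end} outside "
                    f"{self.chrom} (length {chrom_lengths[self.chrom]})")
            if t is SVType.TRA:
                if self.partner_chrom not in chrom_lengths:
                    raise SVValidationError(
                        f"{self.id}: unknown partner chromosome {self.partner_chrom!r}")
                if not 1 <= self.partner_start <= chrom_lengths[self.partner_chrom]:
                    raise SVValidationError(f"{self.id}: partner position outside chromosome")
        return self


def total_length_delta(events: list[SVEvent]) -> int:
    return sum(e.length_delta for e in events)


# ---------------------------------------------------------------------------
# Truth-list TSV I/O
#
# Columns: chrom  pos  type  length  [seq]  [genotype]  [copies]  [ref_span]
# '.' marks an absent optional field; for TRA the seq column holds the partner
# locus as "chrom:pos".
# ---------------------------------------------------------------------------

_TSV_HEADER = "#chrom\tpos\ttype\tlength\tseq\tgenotype\tcopies\tref_span"


def parse_sv_tsv(path, chrom_lengths: dict[str, int] | None = None,
                 min_length: int = MIN_SV_LENGTH) -> list[SVEvent]:
    """Parse a truth-list TSV into validated events; invalid rows raise."""
    events: list[SVEvent] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SVValidationError(f"{path}:{ln}: expected at least 4 columns")
            chrom, pos, svtype, length = fields[:4]
            opt = fields[4:] + ["."] * (4 - len(fields[4:]))
            seq = "" if opt[0] in (".", "") else opt[0].upper()
            gt = Genotype.HOM if opt[1] in (".", "") else Genotype(opt[1])
            copies = 1 if opt[2] in (".", "") else int(opt[2])
            try:
                sv_type = SVType(svtype.upper())
            except ValueError:
                raise SVValidationError(f"{path}:{ln}: unknown SV type {svtype!r}") from None
            length = int(length)
            partner_chrom = partner_start = None
            if sv_type is SVType.TRA:
                if ":" not in seq:
                    raise SVValidationError(f"{path}:{ln}: TRA needs partner 'chrom:pos'")
                partner_chrom, p = seq.rsplit(":", 1)
                partner_start = int(p)
                seq = ""
            ref_span = -1
            if opt[3] not in (".", ""):
                ref_span = int(opt[3])
            elif sv_type is SVType.CSUB:
                ref_span = length  # default: replaced span equals replacement length
            if sv_type in (SVType.INS, SVType.CSUB) and not seq:
                raise SVValidationError(f"{path}:{ln}: {sv_type} requires a sequence")
            ev = SVEvent(id=f"sv{ln}", chrom=chrom, start=int(pos), sv_type=sv_type,
                         length=length, ref_span=ref_span, inserted_seq=seq,
                         copies=copies, genotype=gt,
                         partner_chrom=partner_chrom, partner_start=partner_start)
            events.append(ev.validate(chrom_lengths, min_length=min_length))
    return events


def write_sv_tsv(events: list[SVEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for e in events:
            if e.sv_type is SVType.TRA:
                seq = f"{e.partner_chrom}:{e.partner_start}"
            else:
                seq = e.inserted_seq or "."
            fh.write("\t".join(map(str, [e.chrom, e.start, e.sv_type.value, e.length,
                                         seq, e.genotype.value, e.copies, e.ref_span])) + "\n")


def parse_sv_list(path, reference: dict[str, str] | None = None,
                  min_length: int = MIN_SV_LENGTH) -> list[SVEvent]:
    """Parse a truth list (TSV or VCF, auto-detected) into validated events."""
    from .truthvcf import parse_truth_vcf  # local import: avoids a cycle

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    chrom_lengths = {n: len(s) for n, s in reference.items()} if reference else None
    if first.startswith("##fileformat=VCF"):
        return parse_truth_vcf(path, chrom_lengths=chrom_lengths, min_length=min_length)
    return parse_sv_tsv(path, chrom_lengths=chrom_lengths, min_length=min_length)


__all__ = [
    "SVType", "Genotype", "SVEvent", "SVValidationError", "MIN_SV_LENGTH",
    "parse_sv_list", "parse_sv_tsv", "write_sv_tsv", "total_length_delta", "replace", "field",
]
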