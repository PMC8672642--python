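"""Truth-set VCF output and parsing.

DEL/INS/CSUB are written sequence-resolved with the usual left-anchored
indel encoding (anchor base at POS, deleted/inserted bases following); DUP,
INVDUP and INV use symbolic ALT alleles with SVTYPE/SVLEN/END, and a
reciprocal translocation is emitted as two breakend (BND) pairs sharing an
EVENT id. Genotypes are phased (1|0 = haplotype 1, 0|1 = haplotype 2,
1|1 = homozygous) so a write/parse round trip preserves phasing.
"""

from __future__ import annotations

import re

import pysam

from .events import Genotype, MIN_SV_LENGTH, SVEvent, SVType, SVValidationError

_SAMPLE = "SIM"
_BND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def _build_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Signed length of the variant")
    header.info.add("END", 1, "Integer", "End position of the variant")
    header.info.add("COPIES", 1, "Integer", "Extra copies for duplications")
    header.info.add("REFSPAN", 1, "Integer", "Reference bases replaced (complex substitution)")
    header.info.add("EVENT", 1, "String", "Event id shared by breakend partners")
    header.info.add("MATEID", 1, "String", "Id of the mate breakend")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(_SAMPLE)
    return header


def _gt_tuple(gt: Genotype) -> tuple[int, int]:
    return {Genotype.HET_H1: (1, 0), Genotype.HET_H2: (0, 1), Genotype.HOM: (1, 1)}[gt]


def _set_gt(rec, gt: Genotype) -> None:
    rec.samples[_SAMPLE]["GT"] = _gt_tuple(gt)
    rec.samples[_SAMPLE].phased = True


def write_truth_vcf(events: list[SVEvent], reference: dict[str, str], path) -> None:
    """Write validated events as a VCF 4.2 truth set."""
    contigs = {name: len(seq) for name, seq in reference.items()}
    order = {name: i for i, name in enumerate(contigs)}
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for ev in sorted(events, key=lambda e: (order[e.chrom], e.start, e.id)):
            for rec in _records_for_event(vcf, ev, reference):
                vcf.write(rec)


def _records_for_event(vcf, ev: SVEvent, reference) -> list:
    seq = reference[ev.chrom]
    recs = []

    def new(pos: int, ref: str, alts: tuple[str, ...], stop: int | None = None
            ) -> "pysam.VariantRecord":
        kwargs = {"stop": stop} if stop is not None else {}
        rec = vcf.new_record(contig=ev.chrom, start=pos - 1, alleles=(ref,) + alts,
                             id=ev.id, filter="PASS", **kwargs)
        _set_gt(rec, ev.genotype)
        return rec

    t = ev.sv_type
    if t is SVType.DEL:
        deleted = seq[ev.start - 1:ev.start - 1 + ev.ref_span]
        if ev.start > 1:
            anchor = seq[ev.start - 2]
            rec = new(ev.start - 1, anchor + deleted, (anchor,))
        else:  # no base to the left: anchor on the base after the deletion
            anchor = seq[ev.end]
            rec = new(1, deleted + anchor, (anchor,))
        rec.info["SVTYPE"] = "DEL"
        rec.info["SVLEN"] = -ev.length
        recs.append(rec)
    elif t is SVType.INS:
        anchor = seq[ev.start - 1]
        rec = new(ev.start, anchor, (anchor + ev.inserted_seq,))
        rec.info["SVTYPE"] = "INS"
        rec.info["SVLEN"] = ev.length
        recs.append(rec)
    elif t is SVType.CSUB:
        deleted = seq[ev.start - 1:ev.start - 1 + ev.ref_span]
        if ev.start > 1:
            anchor = seq[ev.start - 2]
            rec = new(ev.start - 1, anchor + deleted, (anchor + ev.inserted_seq,))
        else:
            anchor = seq[ev.end]
            rec = new(1, deleted + anchor, (ev.inserted_seq + anchor,))
        rec.info["SVTYPE"] = "CSUB"
        rec.info["SVLEN"] = ev.length
        rec.info["REFSPAN"] = ev.ref_span
        recs.append(rec)
    elif t in (SVType.DUP, SVType.INVDUP, SVType.INV):
        rec = new(ev.start, seq[ev.start - 1], (f"<{t.value}>",), stop=ev.end)
        rec.info["SVTYPE"] = t.value
        rec.info["SVLEN"] = ev.length
        if t is not SVType.INV:
            rec.info["COPIES"] = ev.copies
        recs.append(rec)
    elif t is SVType.TRA:
        a, b = ev.chrom, ev.partner_chrom
        s, p = ev.start, ev.partner_start
        ref_a = seq[s - 1]
        ref_b = reference[b][p - 1]
        # two reciprocal junction pairs: tail of A joins B at p and vice versa
        alts = [
            (a, s, ref_a, f"{ref_a}[{b}:{p}["),
            (b, p, ref_b, f"]{a}:{s}]{ref_b}"),
            (b, p, ref_b, f"{ref_b}[{a}:{s}["),
            (a, s, ref_a, f"]{b}:{p}]{ref_a}"),
        ]
        mates = [1, 0, 3, 2]
        for i, (chrom, pos, ref, alt) in enumerate(alts):
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt),
                                 id=f"{ev.id}_bnd{i}", filter="PASS")
            _set_gt(rec, ev.genotype)
            rec.info["SVTYPE"] = "BND"
            rec.info["SVLEN"] = ev.length
            rec.info["EVENT"] = ev.id
            rec.info["MATEID"] = f"{ev.id}_bnd{mates[i]}"
            recs.append(rec)
    else:  # pragma: no cover - enum is exhaustive
        raise SVValidationError(f"unsupported SV type {t}")
    return recs


def _genotype_from_record(rec) -> Genotype:
    sample = rec.samples[_SAMPLE] if _SAMPLE in rec.samples else rec.samples[0]
    gt = sample.get("GT")
    if gt == (1, 1):
        return Genotype.HOM
    if gt == (0, 1) and sample.phased:
        return Genotype.HET_H2
    return Genotype.HET_H1


def parse_truth_vcf(path, chrom_lengths: dict[str, int] | None = None,
                    min_length: int = MIN_SV_LENGTH) -> list[SVEvent]:
    """Parse a truth VCF back into validated events (inverse of write_truth_vcf)."""
    events: list[SVEvent] = []
    bnd_first: dict[str, object] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            alt = rec.alts[0] if rec.alts else None
            if svtype == "BND":
                event_id = rec.info.get("EVENT", rec.id)
                if event_id not in bnd_first and rec.id.endswith("_bnd0"):
                    bnd_first[event_id] = rec.copy()
                continue
            events.append(_event_from_record(rec, svtype, alt))
    for event_id, rec in bnd_first.items():
        m = _BND_RE.search(rec.alts[0])
        if not m:
            raise SVValidationError(f"{rec.id}: malformed breakend ALT {rec.alts[0]!r}")
        events.append(SVEvent(
            id=event_id, chrom=rec.contig, start=rec.pos, sv_type=SVType.TRA,
            length=abs(rec.info.get("SVLEN", MIN_SV_LENGTH)), ref_span=0,
            genotype=_genotype_from_record(rec),
            partner_chrom=m.group(1), partner_start=int(m.group(2))))
    return [e.validate(chrom_lengths, min_length=min_length) for e in events]


def _event_from_record(rec, svtype, alt) -> SVEvent:
    gt = _genotype_from_record(rec)
    ev_id = rec.id or f"{rec.contig}_{rec.pos}"
    if alt and alt.startswith("<"):
        sv_type = SVType(svtype or alt.strip("<>"))
        length = abs(rec.info["SVLEN"]) if "SVLEN" in rec.info else rec.stop - rec.pos
        return SVEvent(id=ev_id, chrom=rec.contig, start=rec.pos, sv_type=sv_type,
                       length=length, ref_span=length,
                       copies=rec.info.get("COPIES", 1), genotype=gt)
    ref, pos = rec.ref, rec.pos
    if svtype == "CSUB" or (svtype is None and len(ref) > 1 and len(alt) > 1):
        if pos > 1 or ref[0] == alt[0]:  # left-anchored
            inserted, ref_span, start = alt[1:], len(ref) - 1, pos + 1
        else:  # right-anchored at position 1
            inserted, ref_span, start = alt[:-1], len(ref) - 1, 1
        return SVEvent(id=ev_id, chrom=rec.contig, start=start, sv_type=SVType.CSUB,
                       length=len(inserted), ref_span=rec.info.get("REFSPAN", ref_span),
                       inserted_seq=inserted, genotype=gt)
    if len(ref) > len(alt):  # deletion
        if len(alt) != 1:
            raise SVValidationError(f"{ev_id}: unsupported multi-base deletion ALT")
        start = pos + 1 if ref[0] == alt else pos  # right-anchored when anchor trails
        return SVEvent(id=ev_id, chrom=rec.contig, start=start, sv_type=SVType.DEL,
                       length=len(ref) - 1, ref_span=len(ref) - 1, genotype=gt)
    if len(alt) > len(ref):  # insertion after POS
        if len(ref) != 1 or alt[0] != ref:
            raise SVValidationError(f"{ev_id}: unsupported insertion encoding")
        return SVEvent(id=ev_id, chrom=rec.contig, start=pos, sv_type=SVType.INS,
                       length=len(alt) - 1, ref_span=0, inserted_seq=alt[1:], genotype=gt)
    raise SVValidationError(f"{ev_id}: cannot interpret record as a structural variant")
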