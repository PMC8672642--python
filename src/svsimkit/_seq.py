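"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_rc
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return str(_bio_rc(seq))


def encode_bases(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3; anything else (N, lowercase handled upstream) to -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=width)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
        )


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes)
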