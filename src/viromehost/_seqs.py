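"""Small shared sequence utilities (uppercase ACGT alphabet throughout)."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def write_fasta(path, records: dict[str, str]) -> None:
    """Write an id -> sequence mapping as multi-FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer of ``seq`` (sorted ascending per k-mer)."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index
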