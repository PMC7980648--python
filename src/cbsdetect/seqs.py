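"""Sequence containers and DNA encoding helpers.

Sequences are strings over the alphabet {A, C, G, T, N}. For numerical work
they are packed into ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4); the
numeric order of the four real bases coincides with their lexicographic
order, which the canonical k-mer machinery in :mod:`cbsdetect.sketch` relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)

# complement in code space; N maps to N
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array (A=0..T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if codes.size and codes.max() == 255:
        bad = chr(int(raw[codes == 255][0]))
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@dataclass
class GenomeSequence:
    """A named DNA sequence (reference genome, MAG or masked consensus)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        encode(self.seq)  # alphabet validation

    @property
    def length(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        return encode(self.seq)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read all records of a FASTA file."""
    genomes = [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write genomes as FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")
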