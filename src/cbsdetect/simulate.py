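"""Synthetic genomes, diverged genome pairs and shotgun read sets.

This module produces the controlled inputs the rest of the pipeline is
tested against: random genomes, substitution-only mutants with an exactly
known nucleotide identity, and read sets drawn at a known (Poisson) coverage
with a uniform per-base substitution error rate. Because mutation and
sequencing error are substitution-only, the true ANI between a member genome
and its ancestor is exact, which is what makes the downstream ANI estimators
verifiable against ground truth.

Read starts are drawn on a circularized genome by default so that per-base
depth is stationary (no edge effects in Lander-Waterman checks); pass
``circular=False`` for clipped linear sampling. Quality strings are constant
("I", Phred 40) since no stage of the pipeline consumes base qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqs import COMPLEMENT, GenomeSequence, decode, encode

__all__ = [
    "ReadSet",
    "CommunityMember",
    "CommunityTruth",
    "generate_genome",
    "mutate_genome",
    "simulate_reads",
    "simulate_community",
    "read_fastq",
    "write_fastq",
    "write_truth_table",
    "read_truth_table",
]

_QUAL_CHAR = "I"


@dataclass
class ReadSet:
    """A per-sample collection of reads: (read_id, sequence, quality)."""

    sample_id: str
    reads: list[tuple[str, str, str]] = field(default_factory=list)
    layout: str = "single"

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "paired" and len(self.reads) % 2 != 0:
            raise ValueError("paired layout requires an even read count")
        for rid, seq, qual in self.reads:
            if not seq:
                raise ValueError(f"read {rid!r} has empty sequence")
            if len(seq) != len(qual):
                raise ValueError(f"read {rid!r}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CommunityMember:
    genome_id: str
    true_ani: float
    coverage: float
    present: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_ani <= 1.0:
            raise ValueError("true_ani must be in [0, 1]")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if not self.present and self.coverage != 0:
            raise ValueError("absent members must have coverage 0")


@dataclass
class CommunityTruth:
    """Ground truth for one synthetic community sample."""

    members: list[CommunityMember]
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0
    layout: str = "single"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def derive_member_seed(master_seed: int, index: int) -> int:
    """Per-member stream seed derived from the master seed by a fixed offset."""
    return (master_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1)


def generate_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0, id: str | None = None
) -> GenomeSequence:
    """Random i.i.d. genome with P(G)+P(C) = ``gc_fraction`` split evenly."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    codes = _rng(seed).choice(4, size=length, p=p).astype(np.uint8)
    return GenomeSequence(id or f"genome-{seed}", decode(codes))


def mutate_genome(
    genome: GenomeSequence,
    subst_rate: float,
    seed: int = 0,
    id: str | None = None,
) -> tuple[GenomeSequence, float]:
    """Substitution-only mutant plus the exactly realized identity.

    Each A/C/G/T base is independently substituted with probability
    ``subst_rate`` to one of the three other bases (N positions are left
    untouched). The returned identity is 1 - substituted/length, counted
    exactly, so it can serve as the true ANI in recovery tests.
    """
    if not 0.0 <= subst_rate < 1.0:
        raise ValueError("subst_rate must be in [0, 1)")
    codes = genome.codes()
    rng = _rng(seed)
    hit = (rng.random(codes.size) < subst_rate) & (codes < 4)
    n_sub = int(hit.sum())
    shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
    out = codes.copy()
    out[hit] = (out[hit] + shifts) % 4
    realized = 1.0 - n_sub / codes.size
    return GenomeSequence(id or f"{genome.id}-mut{seed}", decode(out)), realized


def _apply_errors(
    codes2d: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if error_rate <= 0:
        return codes2d
    err = (rng.random(codes2d.shape) < error_rate) & (codes2d < 4)
    n = int(err.sum())
    shifts = rng.integers(1, 4, size=n).astype(np.uint8)
    codes2d = codes2d.copy()
    codes2d[err] = (codes2d[err] + shifts) % 4
    return codes2d


def simulate_reads(
    genome: GenomeSequence,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    layout: str = "single",
    seed: int = 0,
    circular: bool = True,
    sample_id: str | None = None,
) -> ReadSet:
    """Draw reads at uniform random starts to a target mean depth.

    N = round(coverage * genome_length / read_length) reads in total (for the
    paired layout the count is rounded down to an even number and emitted as
    mate pairs of a forward/reverse fragment). Strands are random. Read ids
    encode the source genome, index, start and strand (``src|i|start|+``) so
    ground truth can be recovered downstream.
    """
    if read_length > genome.length:
        raise ValueError("read_length exceeds genome length")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    if layout not in ("single", "paired"):
        raise ValueError(f"unknown layout {layout!r}")

    gcodes = genome.codes()
    L = genome.length
    rng = _rng(seed)
    n_total = int(round(coverage * L / read_length))
    sample = sample_id or f"{genome.id}-reads"
    qual = _QUAL_CHAR * read_length

    if n_total == 0:
        return ReadSet(sample, [], layout)

    reads: list[tuple[str, str, str]] = []
    if layout == "single":
        hi = L if circular else L - read_length + 1
        starts = rng.integers(0, hi, size=n_total)
        strands = rng.integers(0, 2, size=n_total)
        idx = (starts[:, None] + np.arange(read_length)) % L
        mat = gcodes[idx]
        rc = COMPLEMENT[mat][:, ::-1]
        mat = np.where(strands[:, None] == 1, rc, mat)
        mat = _apply_errors(mat, error_rate, rng)
        for i in range(n_total):
            sym = "-" if strands[i] else "+"
            rid = f"{genome.id}|{i}|{int(starts[i])}|{sym}"
            reads.append((rid, decode(mat[i]), qual))
    else:
        frag_len = min(2 * read_length, L)
        n_pairs = n_total // 2
        hi = L if circular else L - frag_len + 1
        starts = rng.integers(0, hi, size=n_pairs)
        idx1 = (starts[:, None] + np.arange(read_length)) % L
        idx2 = (starts[:, None] + frag_len - read_length + np.arange(read_length)) % L
        m1 = _apply_errors(gcodes[idx1], error_rate, rng)
        m2 = _apply_errors(COMPLEMENT[gcodes[idx2]][:, ::-1], error_rate, rng)
        for i in range(n_pairs):
            base = f"{genome.id}|{i}|{int(starts[i])}"
            reads.append((f"{base}/1", decode(m1[i]), qual))
            reads.append((f"{base}/2", decode(m2[i]), qual))
    return ReadSet(sample, reads, layout)


def simulate_community(
    truth: CommunityTruth,
    genomes: Sequence[GenomeSequence] | Mapping[str, GenomeSequence],
    sample_id: str | None = None,
    circular: bool = True,
) -> ReadSet:
    """Union of per-member read sets, deterministically shuffled.

    ``genomes`` must resolve every member ``genome_id`` (members are usually
    mutants of the community's reference representatives). Per-member random
    streams are derived from the master seed by fixed offsets.
    """
    if isinstance(genomes, Mapping):
        by_id = dict(genomes)
    else:
        by_id = {g.id: g for g in genomes}
    reads: list[tuple[str, str, str]] = []
    for i, member in enumerate(truth.members):
        if member.genome_id not in by_id:
            raise KeyError(f"unknown genome_id {member.genome_id!r}")
        if not member.present:
            continue
        rs = simulate_reads(
            by_id[member.genome_id],
            member.coverage,
            read_length=truth.read_length,
            error_rate=truth.error_rate,
            layout=truth.layout,
            seed=derive_member_seed(truth.seed, i),
            circular=circular,
        )
        reads.extend(rs.reads)
    order = _rng(truth.seed).permutation(len(reads))
    if truth.layout == "paired":
        # keep mates adjacent: permute pairs, not reads
        order = _rng(truth.seed).permutation(len(reads) // 2)
        reads = [reads[2 * j + m] for j in order for m in (0, 1)]
    else:
        reads = [reads[j] for j in order]
    return ReadSet(sample_id or f"community-{truth.seed}", reads, truth.layout)


def source_genome_id(read_id: str) -> str:
    """Recover the source genome encoded in a simulated read id."""
    return read_id.split("|", 1)[0]


def planted_sample(
    seed: int,
    n_present: int = 5,
    n_absent: int = 5,
    genome_length: int = 100_000,
    coverages: Sequence[float] = (5, 6, 8, 10, 12),
    mutation_rates: Sequence[float] = (0.0, 0.001, 0.0, 0.001, 0.001),
    read_length: int = 150,
    error_rate: float = 0.002,
) -> tuple[list[GenomeSequence], CommunityTruth, ReadSet]:
    """One planted community: representatives, ground truth and reads.

    ``n_present`` members are substitution-only mutants of distinct
    representatives at the given coverages and mutation rates; the remaining
    representatives have no reads. The defaults emulate a deeply sequenced
    community whose members sit just inside the species boundary of their
    representatives (true ANI 0.999-1.0), with a NovaSeq-like read length
    and a uniform 0.2% substitution error rate.
    """
    if n_present > min(len(coverages), len(mutation_rates)):
        raise ValueError("need a coverage and mutation rate per present member")
    reps = [
        generate_genome(genome_length, 0.5, seed=seed * 1000 + i, id=f"rep{i:02d}")
        for i in range(n_present + n_absent)
    ]
    members: list[CommunityMember] = []
    genomes: dict[str, GenomeSequence] = {}
    for i, rep in enumerate(reps):
        mid = f"member{i:02d}"
        if i < n_present:
            mut, ident = mutate_genome(
                rep, mutation_rates[i], seed=seed * 2000 + i, id=mid
            )
            genomes[mid] = mut
            members.append(CommunityMember(mid, ident, float(coverages[i]), True))
        else:
            genomes[mid] = GenomeSequence(mid, rep.seq)
            members.append(CommunityMember(mid, 1.0, 0.0, False))
    truth = CommunityTruth(
        members, read_length=read_length, error_rate=error_rate, seed=seed
    )
    reads = simulate_community(truth, genomes, sample_id=f"sample-{seed}")
    return reps, truth, reads


# ---------------------------------------------------------------------------
# I/O


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        qual = "".join(chr(q + 33) for q in quals)
        reads.append((rec.id, str(rec.seq).upper(), qual))
    return ReadSet(sample_id or Path(path).stem, reads)


def write_truth_table(truth: CommunityTruth, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genome_id": [m.genome_id for m in truth.members],
            "true_ani": [m.true_ani for m in truth.members],
            "coverage": [m.coverage for m in truth.members],
            "present": [m.present for m in truth.members],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(
    path: str | Path, read_length: int = 150, error_rate: float = 0.0, seed: int = 0
) -> CommunityTruth:
    df = pd.read_csv(path, sep="\t")
    members = [
        CommunityMember(r.genome_id, float(r.true_ani), float(r.coverage), bool(r.present))
        for r in df.itertuples()
    ]
    return CommunityTruth(members, read_length=read_length, error_rate=error_rate, seed=seed)
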