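"""Bottom-hash MinHash sketching and containment screening.

A genome is summarized by the ``s`` smallest distinct 64-bit hashes of its
canonical k-mers (bottom sketch). Screening asks what fraction ``w/s`` of
those hashes also occurs among the k-mers of a read set: the containment
score. Because a random k-mer survives intact in the read set only if every
one of its k bases is correct, containment ``c`` relates to nucleotide
identity roughly as ``identity = c**(1/k)``, which is the identity proxy
reported alongside the score. The median multiplicity of the shared hashes
in the read k-mer multiset serves as a genome-coverage proxy.

Hashing: k-mers are packed into 2 bits/base and passed through the (bijective)
64-bit murmur3 finalizer, XOR-seeded with a fixed documented constant
(:data:`HASH_SEED`). Bijectivity means distinct k-mers never collide, so
distinct-hash counts equal distinct-k-mer counts exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .seqs import GenomeSequence, encode
from .simulate import ReadSet

__all__ = [
    "HASH_SEED",
    "Sketch",
    "ScreenResult",
    "canonical_kmer_hashes",
    "build_sketch",
    "ReadKmerTable",
    "screen",
    "containment_pvalue",
]

#: fixed seed constant XORed into the hash input for reproducibility
HASH_SEED = np.uint64(0x2545F4914F6CDD1D)

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_S33 = np.uint64(33)


def _mix64(x: np.ndarray) -> np.ndarray:
    """Murmur3 64-bit finalizer (a bijection on uint64)."""
    x = np.asarray(x, dtype=np.uint64) ^ HASH_SEED
    x = (x ^ (x >> _S33)) * _M1
    x = (x ^ (x >> _S33)) * _M2
    return x ^ (x >> _S33)


def _canonical_kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-min) 2-bit-packed k-mer values of valid windows.

    Works on a 1-D code array or a 2-D batch of equal-length rows; windows
    containing N are dropped. Returns a flat uint64 array (a multiset).
    """
    codes = np.asarray(codes)
    n = codes.shape[-1] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    u = codes.astype(np.uint64)
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.zeros(codes.shape[:-1] + (n,), dtype=np.uint64)
    rev = np.zeros_like(fwd)
    for i in range(k):
        fwd = (fwd << two) | u[..., i : i + n]
        rev = (rev << two) | (three - u[..., k - 1 - i : k - 1 - i + n])
    canon = np.minimum(fwd, rev)
    is_n = (codes > 3).astype(np.int32)
    cs = np.cumsum(is_n, axis=-1)
    pad = np.zeros(codes.shape[:-1] + (1,), dtype=np.int32)
    cs = np.concatenate([pad, cs], axis=-1)
    valid = (cs[..., k:] - cs[..., :n]) == 0
    return canon[valid].ravel()


def canonical_kmer_hashes(seq: str | np.ndarray, k: int) -> np.ndarray:
    """Hash multiset of the canonical k-mers of one sequence.

    Each window of length k over {A,C,G,T} contributes the hash of
    min(kmer, revcomp(kmer)); windows containing N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packing into 64 bits)")
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    return _mix64(_canonical_kmer_values(codes, k))


@dataclass
class Sketch:
    """Bottom-hash sketch: the s smallest distinct canonical k-mer hashes."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted, strictly increasing uint64
    n_distinct_kmers: int

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > 1 and not (np.diff(self.hashes.astype(np.int64)) != 0).all():
            raise ValueError("sketch hashes must be distinct")
        if len(self.hashes) != min(self.s, self.n_distinct_kmers):
            raise ValueError("|hashes| must equal min(s, n_distinct_kmers)")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "genome_id": self.genome_id,
            "k": self.k,
            "s": self.s,
            "hashes": [int(h) for h in self.hashes],
            "n_distinct_kmers": self.n_distinct_kmers,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "Sketch":
        obj = json.loads(Path(path).read_text())
        return cls(
            obj["genome_id"],
            obj["k"],
            obj["s"],
            np.array(obj["hashes"], dtype=np.uint64),
            obj["n_distinct_kmers"],
        )


def build_sketch(genome: GenomeSequence, k: int = 21, s: int = 10000) -> Sketch:
    """Sketch a genome: retain the s smallest distinct canonical k-mer hashes.

    k must be odd so no k-mer is its own reverse complement and the canonical
    form is unambiguous.
    """
    if k % 2 == 0:
        raise ValueError("sketch k must be odd")
    hashes = np.unique(canonical_kmer_hashes(genome.seq, k))
    n_distinct = int(hashes.size)
    return Sketch(genome.id, k, s, hashes[: min(s, n_distinct)], n_distinct)


@dataclass
class ScreenResult:
    """Containment of one genome sketch in a read set."""

    genome_id: str
    shared: int
    containment: float
    identity: float
    median_multiplicity: float
    p_value: float


class ReadKmerTable:
    """Distinct canonical k-mer hashes of a read set, with multiplicities.

    Built once per (sample, k) and reused across all sketches screened
    against that sample.
    """

    def __init__(self, reads: ReadSet | Sequence[tuple[str, str, str]], k: int):
        if isinstance(reads, ReadSet):
            reads = reads.reads
        self.k = k
        chunks: list[np.ndarray] = []
        by_len: dict[int, list[str]] = {}
        for _rid, seq, _q in reads:
            by_len.setdefault(len(seq), []).append(seq)
        for ln, seqs in by_len.items():
            codes = encode("".join(seqs)).reshape(len(seqs), ln)
            chunks.append(canonical_kmer_hashes(codes, k))
        if chunks:
            allh = np.concatenate(chunks)
            self.hashes, self.counts = np.unique(allh, return_counts=True)
        else:
            self.hashes = np.empty(0, dtype=np.uint64)
            self.counts = np.empty(0, dtype=np.int64)
        self.n_distinct = int(self.hashes.size)

    def multiplicities(self, query: np.ndarray) -> np.ndarray:
        """Occurrence count in the read k-mer multiset for each query hash."""
        if self.n_distinct == 0:
            return np.zeros(len(query), dtype=np.int64)
        pos = np.searchsorted(self.hashes, query)
        pos = np.clip(pos, 0, self.n_distinct - 1)
        found = self.hashes[pos] == query
        out = np.zeros(len(query), dtype=np.int64)
        out[found] = self.counts[pos[found]]
        return out


def containment_pvalue(w: int, s: int, k: int, n_readset_kmers: int) -> float:
    """Upper-tail P(W >= w) for W ~ Binomial(s, r) under the chance-sharing null.

    r is the probability that one random canonical k-mer hash occurs at least
    once among ``n_readset_kmers`` distinct read k-mers: r = 1 - (1 - 4^-k)^n.
    """
    if not 0 <= w <= s:
        raise ValueError("w must be in [0, s]")
    if w == 0:
        return 1.0
    if n_readset_kmers <= 0:
        return 0.0
    r = -np.expm1(n_readset_kmers * np.log1p(-(4.0 ** -k)))
    return float(stats.binom.sf(w - 1, s, r))


def screen(
    sketch: Sketch,
    reads: ReadSet | ReadKmerTable,
    k: int | None = None,
) -> ScreenResult:
    """Containment of a sketch in a read set.

    ``w`` = number of sketch hashes occurring at least once among the read
    k-mer hashes; containment = w/|hashes|; identity = containment**(1/k)
    (0 when w = 0); median multiplicity over the shared hashes only.
    """
    k = k if k is not None else sketch.k
    if k != sketch.k:
        raise ValueError(f"k={k} does not match sketch.k={sketch.k}")
    table = reads if isinstance(reads, ReadKmerTable) else ReadKmerTable(reads, k)
    if table.k != k:
        raise ValueError("read k-mer table was built with a different k")
    mult = table.multiplicities(sketch.hashes)
    shared = mult > 0
    w = int(shared.sum())
    denom = len(sketch.hashes)
    containment = w / denom if denom else 0.0
    identity = containment ** (1.0 / k) if w > 0 else 0.0
    med = float(np.median(mult[shared])) if w > 0 else 0.0
    p = containment_pvalue(w, denom, k, table.n_distinct)
    return ScreenResult(sketch.genome_id, w, containment, identity, med, p)
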