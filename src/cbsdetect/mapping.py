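"""Read alignment, depth profiles and breadth-of-coverage.

The built-in mapper is a deterministic substitution-only seed-and-extend
aligner: exact k-mer seeds from an index of the reference anchor candidate
placements for each read (both strands); each candidate is scored by Hamming
distance over the full read, and the best placement is kept if its mismatch
fraction is at or below the threshold. Unaligned reads are dropped. Ties are
broken by fewest mismatches, then leftmost reference position, then forward
strand, which makes the output order-independent and reproducible.

Alignments from real aligners can be ingested from SAM instead; gapped or
clipped records are projected onto their reference span.

Breadth of coverage B_n is the fraction of reference bases covered at depth
>= n; with reads at Poisson coverage c it converges to the Lander-Waterman
value 1 - CDF_Poisson(n-1; c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .seqs import COMPLEMENT, GenomeSequence, encode
from .simulate import ReadSet

__all__ = [
    "AlignmentRecord",
    "DepthProfile",
    "BreadthResult",
    "ReferenceIndex",
    "map_reads",
    "depth_profile",
    "breadth_at_depth",
    "breadth_result",
    "zero_coverage_regions",
    "mapped_fractions",
    "read_sam",
    "write_bed",
]


@dataclass
class AlignmentRecord:
    """One gapless (or reference-projected) read placement."""

    read_id: str
    ref_id: str
    ref_start: int  # 0-based
    ref_end: int  # 0-based exclusive
    read_codes: np.ndarray  # reference-oriented base codes for covered positions
    n_mismatches: int
    strand: str = "+"
    # set only for gapped SAM records: absolute reference positions of each
    # aligned read base (same length as read_codes); None means contiguous
    ref_positions: np.ndarray | None = None

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class DepthProfile:
    """Per-base coverage depth over one reference."""

    ref_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass
class BreadthResult:
    """Breadth-of-coverage curve plus depth summaries for one reference."""

    ref_id: str
    breadth: dict[int, float]
    mapped_reads: int
    mean_depth: float
    sd_depth: float
    q1: float
    median_depth: float
    q3: float


class ReferenceIndex:
    """Sorted exact-match seed index over the forward strand of a reference."""

    def __init__(self, reference: GenomeSequence, seed_length: int = 21):
        if seed_length < 1 or seed_length > 31:
            raise ValueError("seed_length must be in [1, 31]")
        self.reference = reference
        self.seed_length = seed_length
        self.codes = reference.codes()
        L = self.codes.size
        n = L - seed_length + 1
        if n <= 0:
            raise ValueError("reference shorter than seed length")
        kmers = _packed_kmers(self.codes, seed_length)
        valid = _valid_windows(self.codes, seed_length)
        positions = np.nonzero(valid)[0]
        kmers = kmers[valid]
        if kmers.size == 0:
            raise ValueError("empty reference index (no N-free seed windows)")
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_positions = positions[order]


def _packed_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed forward k-mers of every window (rows batched if 2-D)."""
    u = np.asarray(codes).astype(np.uint64)
    n = u.shape[-1] - k + 1
    out = np.zeros(u.shape[:-1] + (n,), dtype=np.uint64)
    two = np.uint64(2)
    for i in range(k):
        out = (out << two) | u[..., i : i + n]
    return out


def _valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    is_n = (np.asarray(codes) > 3).astype(np.int32)
    cs = np.cumsum(is_n, axis=-1)
    pad = np.zeros(is_n.shape[:-1] + (1,), dtype=np.int32)
    cs = np.concatenate([pad, cs], axis=-1)
    n = codes.shape[-1] - k + 1
    return (cs[..., k:] - cs[..., :n]) == 0


def map_reads(
    reads: ReadSet | Sequence[tuple[str, str, str]],
    reference: GenomeSequence | ReferenceIndex,
    seed_length: int = 21,
    max_mismatch_frac: float = 0.10,
    n_seeds: int = 6,
) -> list[AlignmentRecord]:
    """Best-hit substitution-only alignment of reads against one reference.

    Candidate placements come from up to ``n_seeds`` evenly spaced exact seed
    matches per strand; the best candidate (fewest mismatches, then leftmost,
    then forward strand) is retained when its mismatch fraction is
    <= ``max_mismatch_frac``. Reads with no acceptable placement are omitted.
    """
    if isinstance(reference, ReferenceIndex):
        index = reference
        if seed_length != index.seed_length:
            seed_length = index.seed_length
    else:
        index = ReferenceIndex(reference, seed_length)
    read_list = reads.reads if isinstance(reads, ReadSet) else list(reads)
    if not read_list:
        return []

    L = index.codes.size
    out: list[AlignmentRecord] = []
    by_len: dict[int, list[int]] = {}
    for i, (_rid, seq, _q) in enumerate(read_list):
        by_len.setdefault(len(seq), []).append(i)

    for rl, idxs in by_len.items():
        if seed_length > rl or rl > L:
            continue
        rows = np.array(idxs)
        fwd = encode("".join(read_list[i][1] for i in idxs)).reshape(len(idxs), rl)
        rc = COMPLEMENT[fwd][:, ::-1]
        offsets = np.unique(np.linspace(0, rl - seed_length, n_seeds).astype(int))

        cand_read: list[np.ndarray] = []
        cand_start: list[np.ndarray] = []
        cand_strand: list[np.ndarray] = []
        for strand_code, mat in ((0, fwd), (1, rc)):
            for off in offsets:
                seg = mat[:, off : off + seed_length]
                ok = (seg < 4).all(axis=1)
                seeds = _packed_kmers(seg, seed_length)[:, 0]
                lo = np.searchsorted(index.sorted_kmers, seeds, side="left")
                hi = np.searchsorted(index.sorted_kmers, seeds, side="right")
                counts = (hi - lo) * ok
                one = counts >= 1
                if one.any():
                    starts = index.sorted_positions[lo[one]] - off
                    cand_read.append(np.nonzero(one)[0])
                    cand_start.append(starts)
                    cand_strand.append(np.full(int(one.sum()), strand_code))
                multi = np.nonzero(counts > 1)[0]
                for r in multi:
                    extra = index.sorted_positions[lo[r] + 1 : hi[r]] - off
                    cand_read.append(np.full(extra.size, r))
                    cand_start.append(extra)
                    cand_strand.append(np.full(extra.size, strand_code))
        if not cand_read:
            continue
        c_read = np.concatenate(cand_read)
        c_start = np.concatenate(cand_start)
        c_strand = np.concatenate(cand_strand)
        in_bounds = (c_start >= 0) & (c_start + rl <= L)
        c_read, c_start, c_strand = c_read[in_bounds], c_start[in_bounds], c_strand[in_bounds]
        if c_read.size == 0:
            continue
        key = (c_read.astype(np.int64) * 2 + c_strand) * (L + rl + 2) + c_start
        _, uniq = np.unique(key, return_index=True)
        c_read, c_start, c_strand = c_read[uniq], c_start[uniq], c_strand[uniq]

        refmat = index.codes[c_start[:, None] + np.arange(rl)]
        readmat = np.where(c_strand[:, None] == 0, fwd[c_read], rc[c_read])
        mm = (readmat != refmat).sum(axis=1)
        accept = mm <= max_mismatch_frac * rl
        c_read, c_start, c_strand, mm = (
            c_read[accept],
            c_start[accept],
            c_strand[accept],
            mm[accept],
        )
        if c_read.size == 0:
            continue
        order = np.lexsort((c_strand, c_start, mm, c_read))
        c_read, c_start, c_strand, mm = (
            c_read[order],
            c_start[order],
            c_strand[order],
            mm[order],
        )
        first = np.ones(c_read.size, dtype=bool)
        first[1:] = c_read[1:] != c_read[:-1]
        for j in np.nonzero(first)[0]:
            r = int(c_read[j])
            gi = int(rows[r])
            strand = "-" if c_strand[j] else "+"
            codes = rc[r] if c_strand[j] else fwd[r]
            out.append(
                AlignmentRecord(
                    read_id=read_list[gi][0],
                    ref_id=index.reference.id,
                    ref_start=int(c_start[j]),
                    ref_end=int(c_start[j]) + rl,
                    read_codes=codes,
                    n_mismatches=int(mm[j]),
                    strand=strand,
                )
            )
    out.sort(key=lambda a: (a.ref_start, a.ref_end, a.read_id))
    return out


def depth_profile(
    alignments: Iterable[AlignmentRecord], reference: GenomeSequence
) -> DepthProfile:
    """Per-base depth: number of alignments covering each position."""
    L = reference.length
    diff = np.zeros(L + 1, dtype=np.int64)
    scatter: list[np.ndarray] = []
    for aln in alignments:
        if aln.ref_id != reference.id:
            raise ValueError(f"alignment {aln.read_id!r} references {aln.ref_id!r}")
        if aln.ref_start < 0 or aln.ref_end > L or aln.ref_start >= aln.ref_end:
            raise ValueError(f"alignment {aln.read_id!r} outside reference bounds")
        if aln.ref_positions is None:
            diff[aln.ref_start] += 1
            diff[aln.ref_end] -= 1
        else:
            scatter.append(aln.ref_positions)
    depth = np.cumsum(diff[:-1])
    if scatter:
        np.add.at(depth, np.concatenate(scatter), 1)
    return DepthProfile(reference.id, depth)


def breadth_at_depth(profile: DepthProfile, n: int) -> float:
    """B_n: fraction of reference bases covered at depth >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.mean(profile.depth >= n))


def breadth_result(
    profile: DepthProfile, mapped_reads: int, max_n: int = 5
) -> BreadthResult:
    d = profile.depth
    q1, med, q3 = (float(q) for q in np.percentile(d, [25, 50, 75]))
    return BreadthResult(
        ref_id=profile.ref_id,
        breadth={n: breadth_at_depth(profile, n) for n in range(1, max_n + 1)},
        mapped_reads=mapped_reads,
        mean_depth=float(d.mean()),
        sd_depth=float(d.std()),
        q1=q1,
        median_depth=med,
        q3=q3,
    )


def zero_coverage_regions(profile: DepthProfile) -> list[tuple[int, int]]:
    """Maximal half-open intervals with zero depth, sorted and disjoint."""
    zero = profile.depth == 0
    if not zero.any():
        return []
    padded = np.concatenate([[False], zero, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def mapped_fractions(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-reference mapped-read fractions, normalized by the summed counts."""
    for cbs, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {cbs!r}")
    total = sum(counts.values())
    if total == 0:
        warnings.warn("all mapped-read counts are zero; fractions set to 0")
        return {cbs: 0.0 for cbs in counts}
    return {cbs: c / total for cbs, c in counts.items()}


def read_sam(
    path: str | Path, reference: GenomeSequence | None = None
) -> list[AlignmentRecord]:
    """Ingest alignments from a SAM file (primary, mapped records only).

    CIGAR M/=/X bases are consumed; indel or clipped records are projected
    onto their reference span via the aligned pairs. Mismatch counts come
    from the NM tag when present, otherwise from comparison against
    ``reference`` (0 if neither is available).
    """
    out: list[AlignmentRecord] = []
    ref_codes = reference.codes() if reference is not None else None
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_sequence is None:
                continue
            qcodes = encode(rec.query_sequence.upper())
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.array([p[0] for p in pairs])
            rpos = np.array([p[1] for p in pairs])
            codes = qcodes[qpos]
            start, end = int(rpos[0]), int(rpos[-1]) + 1
            contiguous = rpos.size == end - start and (np.diff(rpos) == 1).all()
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif ref_codes is not None:
                nm = int((codes != ref_codes[rpos]).sum())
            else:
                nm = 0
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=start,
                    ref_end=end,
                    read_codes=codes,
                    n_mismatches=nm,
                    strand="-" if rec.is_reverse else "+",
                    ref_positions=None if contiguous else rpos,
                )
            )
    return out


def write_bed(
    regions: Iterable[tuple[int, int]], ref_id: str, path: str | Path
) -> None:
    """Write intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for start, end in regions:
            fh.write(f"{ref_id}\t{start}\t{end}\n")
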