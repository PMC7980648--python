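"""Masked consensus calling and fragment-based ANI estimation.

The consensus rewrites a reference with the sample-supported allele at every
covered position (haploid: one allele, majority vote over the pileup, ties
kept as the reference base) and masks zero-coverage positions with N. Because
alignment and calling are substitution-only, the consensus has exactly the
reference length, and the set of N positions equals the set of zero-depth
positions.

ANI between two sequences is estimated fragment-wise: the query is cut into
consecutive fixed-length windows, each window is anchored on the reference by
exact-seed offset voting (both strands), scored by gapless identity at the
anchored offset, and the ANI is the mean identity of the fragments that map
at or above the minimum identity. Windows that are mostly masked (>50% N)
carry no identity information and are excluded from the fragment total; the
masked-consensus-versus-representative ANI computed this way is the ANI_CBS
statistic consumed by the presence rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentRecord, DepthProfile
from .seqs import COMPLEMENT, GenomeSequence, decode, encode

__all__ = [
    "ConsensusSequence",
    "ANIResult",
    "pileup_counts",
    "call_consensus",
    "fragment_ani",
    "consensus_ani",
]


@dataclass
class ConsensusSequence:
    """Masked haploid consensus of a reference from sample alignments."""

    ref_id: str
    seq: str
    n_masked: int
    n_substituted: int

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ANIResult:
    """Fragment-based ANI estimate between a query and a reference."""

    query_id: str
    ref_id: str
    ani: float
    fragments_total: int
    fragments_mapped: int
    fragment_identities: list[float] | None = None

    @property
    def aligned_fraction(self) -> float:
        if self.fragments_total == 0:
            return 0.0
        return self.fragments_mapped / self.fragments_total

    @property
    def defined(self) -> bool:
        """ANI is meaningful only when at least one fragment mapped."""
        return self.fragments_mapped >= 1


def pileup_counts(
    alignments: Iterable[AlignmentRecord], reference: GenomeSequence
) -> np.ndarray:
    """Per-position base counts, shape (4, L); read N bases are ignored."""
    L = reference.length
    counts = np.zeros((4, L), dtype=np.int64)
    starts, mats = [], []
    for aln in alignments:
        if aln.ref_id != reference.id:
            raise ValueError(f"alignment {aln.read_id!r} references {aln.ref_id!r}")
        if aln.ref_positions is not None:
            pos = aln.ref_positions
            codes = aln.read_codes
            keep = codes < 4
            np.add.at(counts, (codes[keep], pos[keep]), 1)
        else:
            starts.append(aln.ref_start)
            mats.append(aln.read_codes)
    if starts:
        # batch contiguous alignments per read length
        by_len: dict[int, list[int]] = {}
        for i, m in enumerate(mats):
            by_len.setdefault(len(m), []).append(i)
        for rl, idxs in by_len.items():
            st = np.array([starts[i] for i in idxs])
            mat = np.stack([mats[i] for i in idxs])
            pos = (st[:, None] + np.arange(rl)).ravel()
            codes = mat.ravel()
            keep = codes < 4
            np.add.at(counts, (codes[keep], pos[keep]), 1)
    return counts


def call_consensus(
    profile: DepthProfile,
    pileup: np.ndarray,
    reference: GenomeSequence,
) -> ConsensusSequence:
    """Majority-vote haploid consensus with zero-coverage masking.

    Positions with zero depth become N; covered positions take the majority
    base of the pileup, with ties resolved in favour of the reference base
    (ties between two non-reference bases go to the smaller base code). The
    output has exactly the reference length.
    """
    pileup = np.asarray(pileup)
    if pileup.shape != (4, reference.length):
        raise ValueError("pileup shape must be (4, reference length)")
    if profile.length != reference.length:
        raise ValueError("profile/reference length mismatch")
    ref_codes = reference.codes()
    depth = profile.depth
    covered = depth > 0

    best = pileup.argmax(axis=0).astype(np.uint8)
    maxc = pileup.max(axis=0)
    ref_clip = np.minimum(ref_codes, 3)
    ref_count = pileup[ref_clip, np.arange(reference.length)]
    ref_wins = (ref_count == maxc) & (ref_codes < 4)

    cons = np.where(ref_wins, ref_codes, best).astype(np.uint8)
    # positions covered by alignments whose bases were all N reads: keep reference
    no_votes = (maxc == 0) & covered
    cons[no_votes] = ref_codes[no_votes]
    cons[~covered] = 4  # N mask

    n_masked = int((~covered).sum())
    n_sub = int(((cons != ref_codes) & covered).sum())
    return ConsensusSequence(reference.id, decode(cons), n_masked, n_sub)


class _SeedIndex:
    """Sorted exact seed index used for fragment anchoring."""

    def __init__(self, codes: np.ndarray, k: int):
        from .mapping import _packed_kmers, _valid_windows

        kmers = _packed_kmers(codes, k)
        valid = _valid_windows(codes, k)
        positions = np.nonzero(valid)[0]
        kmers = kmers[valid]
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.positions = positions[order]

    def lookup(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.kmers, query, side="left")
        hi = np.searchsorted(self.kmers, query, side="right")
        return lo, hi


def fragment_ani(
    query: GenomeSequence,
    reference: GenomeSequence,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
    seed_length: int = 16,
    seed_stride: int = 50,
) -> ANIResult:
    """Fragment-mapping ANI of ``query`` against ``reference``.

    The query is cut into consecutive ``frag_len`` windows (a trailing
    remainder shorter than ``frag_len`` is ignored). Each window is anchored
    on the reference by mode-offset voting over exact ``seed_length``-mer
    matches on both strands (ties: smaller reference offset, forward strand)
    and scored by gapless identity at that offset, ignoring query N
    positions. Fragments with identity >= ``min_frag_identity`` count as
    mapped; ANI is the mean identity over mapped fragments (0.0, flagged
    undefined, when none map). Windows with >50% N are excluded from the
    fragment total.
    """
    if query.length < frag_len:
        raise ValueError("query shorter than one fragment")
    qcodes = query.codes()
    rcodes = reference.codes()
    L_ref = rcodes.size
    index = _SeedIndex(rcodes, seed_length)

    n_windows = qcodes.size // frag_len
    from .mapping import _packed_kmers, _valid_windows

    identities: list[float] = []
    mapped = 0
    total = 0
    for w in range(n_windows):
        frag = qcodes[w * frag_len : (w + 1) * frag_len]
        if (frag > 3).mean() > 0.5:
            continue  # mostly masked: no identity information
        total += 1
        rc_frag = COMPLEMENT[frag][::-1]
        votes: Counter[tuple[int, int]] = Counter()
        seed_offsets = range(0, frag_len - seed_length + 1, seed_stride)
        for strand, fcodes in ((0, frag), (1, rc_frag)):
            kmers = _packed_kmers(fcodes, seed_length)
            valid = _valid_windows(fcodes, seed_length)
            offs = np.array([o for o in seed_offsets if valid[o]])
            if offs.size == 0:
                continue
            lo, hi = index.lookup(kmers[offs])
            for j, o in enumerate(offs):
                for pos in index.positions[lo[j] : hi[j]]:
                    votes[(strand, int(pos) - int(o))] += 1
        if not votes:
            continue
        # mode offset; ties -> smaller reference offset, then forward strand
        best_strand, best_off = min(
            votes, key=lambda so: (-votes[so], so[1], so[0])
        )
        fcodes = rc_frag if best_strand else frag
        lo_q = max(0, -best_off)
        hi_q = min(frag_len, L_ref - best_off)
        if hi_q <= lo_q:
            continue
        qpart = fcodes[lo_q:hi_q]
        rpart = rcodes[best_off + lo_q : best_off + hi_q]
        informative = qpart < 4
        denom = int(informative.sum())
        if denom == 0:
            continue
        ident = float((qpart[informative] == rpart[informative]).mean())
        if ident >= min_frag_identity:
            mapped += 1
            identities.append(ident)
    ani = float(np.mean(identities)) if identities else 0.0
    return ANIResult(query.id, reference.id, ani, total, mapped, identities)


def consensus_ani(
    consensus: ConsensusSequence,
    representative: GenomeSequence,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
) -> ANIResult:
    """ANI_CBS: fragment ANI of the masked consensus against its representative.

    When every fragment is masked away the result is flagged undefined
    (``defined`` False) and must be treated as failing the ANI criterion.
    """
    if consensus.ref_id != representative.id:
        raise ValueError(
            f"consensus is for {consensus.ref_id!r}, not {representative.id!r}"
        )
    query = GenomeSequence(f"{consensus.ref_id}|consensus", consensus.seq)
    res = fragment_ani(
        query, representative, frag_len=frag_len, min_frag_identity=min_frag_identity
    )
    return res


def write_fragment_report(result: ANIResult, path: str | Path) -> None:
    """Per-fragment diagnostics TSV (identity of mapped fragments)."""
    df = pd.DataFrame(
        {
            "fragment_index": range(len(result.fragment_identities or [])),
            "identity": result.fragment_identities or [],
        }
    )
    df.to_csv(path, sep="\t", index=False)
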