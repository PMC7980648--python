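# Methods

## Scope and model

`cbsdetect` detects candidate bacterial species (CBS) in shotgun metagenomes
by combining three independent lines of evidence per (sample, species) pair:
read-mapping breadth of coverage, the ANI of a zero-coverage-masked consensus
to the species representative, and MinHash containment of the representative's
k-mer sketch in the sample's reads. Upstream steps (read QC, assembly,
binning, completeness/contamination estimation, taxonomic placement) are out
of scope; completeness/contamination arrive as input metadata.

## Synthetic data generator

The generator emulates a shotgun study: random i.i.d. genomes with a chosen
GC fraction; substitution-only mutants whose realized identity is counted
exactly (the true ANI for recovery tests); and reads of fixed length drawn at
uniformly random starts and strands, with i.i.d. per-base substitution errors.
Read starts are drawn on the circularized genome so depth is stationary and
Poisson — the Lander–Waterman regime — with a `circular=False` option for
clipped linear sampling. Quality strings are constant (`I`, Phred 40) because
no stage consumes base qualities. Defaults follow the study conditions:
150 bp reads (paired 2×150 available; the paired fragment is two abutting
mates), and community error rates of a few per mille as for patterned
flow-cell instruments.

What the generator does **not** emulate: indels (in either mutation or
error), quality-dependent error profiles, GC-coverage bias, strain mixtures
within one member, and inter-genome homology other than the planted
mutations. Passing tests therefore demonstrate correctness of the statistics
and decision rules under a clean substitution-only model, not robustness to
structural variation or biased real-world coverage.

Per-member random streams are derived from the master seed by a fixed affine
offset, so adding a member never changes the reads of another.

## Sketching and containment

Canonical k-mers (minimum of the forward and reverse-complement 2-bit
packing; windows containing N skipped) are hashed with the 64-bit murmur3
finalizer XOR-seeded by a fixed constant. The finalizer is a bijection on
64-bit integers, so distinct k-mers cannot collide and the bottom sketch of
the `s` smallest distinct hashes is an exact order statistic. Sketch k must
be odd so no k-mer equals its own reverse complement. Defaults: k = 21,
s = 10,000.

Containment of a sketch in a read set is `w/s` where `w` counts sketch hashes
occurring at least once among the read k-mers; the identity proxy is
`c^(1/k)`; the median multiplicity over shared hashes proxies coverage. The
p-value is the upper binomial tail P(W ≥ w) with per-hash chance-occurrence
probability `r = 1 − (1 − 4^(−k))^n` for `n` distinct read k-mers — a fully
specified null that mirrors the published screening statistic.

A note on calibration: with reads of length `rl` at base coverage `c`, the
k-mer coverage is only `c·(rl−k+1)/rl`, and the expected self-containment of
an error-free read set is `exp(−c·(rl−k+1)/rl)` short of 1 — about 0.987 at
c = 5 with 150 bp reads and k = 21. Containment is therefore a *downward
biased* identity proxy at modest depth, which is why the confirmation step is
applied to detections (B₂ ≥ 0.5 implies appreciable depth) rather than used
as the primary presence rule.

## Mapping and breadth

The built-in mapper is substitution-only, best-hit and fully deterministic:
up to six evenly spaced exact 21-mer seeds per strand propose placements, the
full-read Hamming distance scores them, and ties break by fewest mismatches,
then leftmost reference position, then forward strand. Reads above the
mismatch-fraction ceiling (default 0.10) are omitted, mirroring aligners run
without reporting unaligned reads. SAM ingestion (via pysam) supports real
aligners; gapped or clipped records are projected onto the reference through
their aligned pairs.

Breadth `B_n` is the fraction of positions with depth ≥ n, computed for
n = 1..5. The ≥ reading (rather than exactly-n) gives the standard monotone
breadth curve B₁ ≥ B₂ ≥ … and matches the "breadth at depth 2" usage of the
detection rule. Coordinates are 0-based half-open throughout; zero-coverage
intervals are emitted as BED.

## Consensus and ANI

The consensus is haploid: per covered position, the majority base of the
pileup, with ties resolved to the reference base (conservative toward the
representative, as when consensus is rebuilt from a variant file where
non-variant sites keep the reference; ties between two non-reference bases
take the smaller base code). Zero-coverage positions are masked to N, so the
masked set equals the zero-depth set exactly and the consensus preserves the
reference length. No minimum depth above 1 is imposed, and indels are not
called — a deliberate divergence from general-purpose callers that keeps
coordinates aligned and the ANI ground truth exact.

Fragment ANI cuts the query into consecutive 1000 bp windows (1000 rather
than a longer fragment so 10⁵ bp test genomes still yield 100 fragments;
configurable). Each window is anchored on the reference by mode-offset voting
over exact 16-mer seeds every 50 bp on both strands (ties: smaller reference
offset, forward strand), then scored by gapless identity at that offset over
its non-N positions. Fragments with identity ≥ 0.8 count as mapped; ANI is
the mean identity of mapped fragments; windows with more than 50% N are
excluded from the fragment total because masked bases carry no identity
information. When no fragment maps the ANI is flagged undefined, and the
presence rule treats undefined ANI as failing.

## Dereplication and detection

MAGs are tiered HQ (>90% completeness, <5% contamination), MQ (≥50%, <10%)
or discarded; HQ and MQ MAGs are clustered greedily in decreasing
quality-score order, joining the first existing cluster whose representative
exceeds symmetric ANI 0.95 (the mean of the two directed fragment estimates,
an undefined direction counting as 0), else founding a new cluster whose
representative never changes. Greedy centroid clustering is deterministic and
fully specified, and is equivalent to two-stage schemes on well-separated
clusters; no alignment-fraction floor is applied by default since the
synthetic tests control relatedness explicitly. The quality score uses the
conventional dereplication weighting `completeness − 5·contamination +
0.5·log₁₀(N50)` with lexicographic MAG-id tie-break.

Presence: `B₂ ≥ 0.5 ∧ ANI_CBS ≥ 0.95`, both inclusive. Confirmation:
containment strictly > 0.95 and p-value strictly below the ceiling; the
default ceiling 1.47×10⁻²¹ is a dataset-derived constant and therefore
exposed in the configuration. Core species require presence (mapping or
assembly) in ≥ ⌈0.75·n⌉ samples — 14 of 18 for an 18-sample study. Detection
events are reported per (sample, CBS); prevalence is reported per CBS.

## Numerical and design choices

- All sequence math runs on uint8 code arrays (A=0..T=3, N=4); k-mers pack
  into uint64, so k ≤ 31.
- Reads are aligned to each representative independently; a read may count
  for several CBS, and mapped-read fractions are normalized by the summed
  per-CBS counts.
- Reads that wrap the circular origin of a simulated genome cannot align to
  the linear reference and are dropped (~0.15% at 150 bp/10⁵ bp); the effect
  on breadth is ~10⁻⁴.
- `mapped_fractions` of an all-zero count vector returns zeros with a
  warning rather than raising.
- Test and calibration problem sizes — 10⁵ bp genomes, coverages 2–20, five
  planted communities of ten species — keep every stage's sampling error an
  order of magnitude below the asserted tolerances while the full suite runs
  in well under a minute per module.
- The planted communities used for end-to-end recovery place present members
  at coverages 5–12 and true ANI 0.999–1.0 with a 0.2% error rate: deep
  enough that the closed-form expected containment
  (`ANI^k · (1 − exp(−c·(rl−k+1)/rl·(1−e)^k))` ≈ 0.96–0.999) clears the 0.95
  confirmation bound with margin, while B₂ and ANI_CBS sit far inside their
  thresholds. Detection-only recovery (without confirmation) additionally
  holds down to coverage 2 at ANI 0.995, where E[B₂] ≈ 0.59.

## Known limitations

Substitution-only alignment and consensus mean real indel-rich divergence
will read as mismatch clusters; the built-in mapper is not a general aligner
(use SAM ingestion for real data); containment is downward biased at low
depth as noted above; and greedy clustering can split clusters whose members
chain between two representatives near the threshold.
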