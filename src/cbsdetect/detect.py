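"""MAG quality tiers, species dereplication, presence calls and prevalence.

MAGs are tiered by CheckM-style completeness/contamination estimates:
high-quality (HQ) drafts have >90% completeness and <5% contamination,
medium-quality (MQ) drafts >=50% completeness and <10% contamination,
anything else is discarded. HQ and MQ MAGs are dereplicated into candidate
bacterial species (CBS) at >95% ANI by greedy centroid clustering in
decreasing quality-score order; each cluster is represented by its
highest-scoring member (the score is completeness - 5*contamination +
0.5*log10(N50), with ties broken by MAG id).

A CBS is called present in a sample when the breadth of coverage at depth 2
satisfies B2 >= 0.5 and the masked-consensus ANI satisfies ANI_CBS >= 0.95
(both inclusive). Detections are independently confirmed by sketch screening
(containment strictly > 0.95 and p-value strictly below a configurable
ceiling). Prevalence combines mapping presence with assembly evidence (a
member MAG recovered from the sample); core species are those present in at
least ceil(core_fraction * n_samples) samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import fragment_ani
from .seqs import GenomeSequence
from .sketch import ScreenResult

__all__ = [
    "MAGRecord",
    "SpeciesCluster",
    "DetectionCall",
    "PrevalenceTable",
    "ConcordanceReport",
    "classify_quality",
    "quality_score",
    "dereplicate",
    "symmetric_ani",
    "detect_presence",
    "confirm_with_screen",
    "prevalence_and_core",
    "concordance_report",
    "abundance_summary",
    "read_mag_table",
]

DEFAULT_MAX_PVALUE = 1.47e-21  # dataset-derived ceiling; configurable


def classify_quality(completeness: float, contamination: float) -> str:
    """Tier a MAG: 'HQ', 'MQ' or 'discarded'.

    HQ requires >90% completeness and <5% contamination; MQ requires >=50%
    completeness and <10% contamination (strict/inclusive bounds as stated).
    """
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be >= 0")
    if completeness > 90 and contamination < 5:
        return "HQ"
    if completeness >= 50 and contamination < 10:
        return "MQ"
    return "discarded"


@dataclass
class MAGRecord:
    """A MAG with its quality metadata (estimates are inputs, not computed)."""

    mag_id: str
    sample_id: str
    completeness: float
    contamination: float
    n50: int
    tier: str = field(init=False)

    def __post_init__(self) -> None:
        if self.n50 < 1:
            raise ValueError("n50 must be >= 1")
        self.tier = classify_quality(self.completeness, self.contamination)


def quality_score(mag: MAGRecord) -> float:
    """completeness - 5*contamination + 0.5*log10(N50)."""
    return mag.completeness - 5.0 * mag.contamination + 0.5 * math.log10(mag.n50)


@dataclass
class SpeciesCluster:
    """A >95%-ANI species cluster with a fixed representative MAG."""

    cbs_id: str
    member_mag_ids: list[str]
    representative_mag_id: str

    def __post_init__(self) -> None:
        if not self.member_mag_ids:
            raise ValueError("cluster must have members")
        if self.representative_mag_id not in self.member_mag_ids:
            raise ValueError("representative must be a member")


def symmetric_ani(
    a: GenomeSequence,
    b: GenomeSequence,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
) -> float:
    """Mean of the two directed fragment-ANI estimates (undefined -> 0)."""
    r1 = fragment_ani(a, b, frag_len=frag_len, min_frag_identity=min_frag_identity)
    r2 = fragment_ani(b, a, frag_len=frag_len, min_frag_identity=min_frag_identity)
    v1 = r1.ani if r1.defined else 0.0
    v2 = r2.ani if r2.defined else 0.0
    return (v1 + v2) / 2.0


def dereplicate(
    mags: Sequence[MAGRecord],
    genomes: Mapping[str, GenomeSequence],
    ani_threshold: float = 0.95,
    frag_len: int = 1000,
    min_frag_identity: float = 0.8,
) -> list[SpeciesCluster]:
    """Greedy centroid clustering of MAGs at species level.

    MAGs are processed in decreasing quality-score order (ties by mag_id);
    each MAG joins the first existing cluster whose representative it matches
    at symmetric ANI strictly above ``ani_threshold``, otherwise it founds a
    new cluster and becomes its (permanent) representative. Discarded-tier
    MAGs must be excluded by the caller.
    """
    for mag in mags:
        if mag.mag_id not in genomes:
            raise KeyError(f"no genome for MAG {mag.mag_id!r}")
        if mag.tier == "discarded":
            raise ValueError(f"MAG {mag.mag_id!r} is discarded-tier; exclude it")
    order = sorted(mags, key=lambda m: (-quality_score(m), m.mag_id))
    clusters: list[SpeciesCluster] = []
    for mag in order:
        placed = False
        for cluster in clusters:
            rep = genomes[cluster.representative_mag_id]
            ani = symmetric_ani(
                genomes[mag.mag_id],
                rep,
                frag_len=frag_len,
                min_frag_identity=min_frag_identity,
            )
            if ani > ani_threshold:
                cluster.member_mag_ids.append(mag.mag_id)
                placed = True
                break
        if not placed:
            clusters.append(
                SpeciesCluster(
                    cbs_id=f"CBS_{mag.mag_id}",
                    member_mag_ids=[mag.mag_id],
                    representative_mag_id=mag.mag_id,
                )
            )
    return clusters


@dataclass
class DetectionCall:
    """Per (sample, CBS) presence decision with its evidence."""

    sample_id: str
    cbs_id: str
    b2: float
    ani_cbs: float | None
    present_by_mapping: bool
    present_by_assembly: bool = False
    confirmed_by_screen: bool | None = None  # None = not evaluated


def detect_presence(b2: float, ani_cbs: float | None) -> bool:
    """Presence rule: B2 >= 0.5 and ANI_CBS defined and >= 0.95 (inclusive)."""
    if not 0.0 <= b2 <= 1.0:
        raise ValueError("b2 must be in [0, 1]")
    return b2 >= 0.5 and ani_cbs is not None and ani_cbs >= 0.95


def confirm_with_screen(
    call: DetectionCall,
    screen: ScreenResult,
    min_containment: float = 0.95,
    max_pvalue: float = DEFAULT_MAX_PVALUE,
) -> bool:
    """Screen confirmation: containment strictly > 0.95 and p strictly < ceiling."""
    if not call.present_by_mapping:
        raise ValueError("confirmation is evaluated for detections only")
    return screen.containment > min_containment and screen.p_value < max_pvalue


@dataclass
class PrevalenceTable:
    """Study-wide boolean presence matrix with per-cell evidence labels."""

    samples: list[str]
    cbs: list[str]
    cells: np.ndarray  # bool, shape (n_cbs, n_samples)
    evidence: np.ndarray  # str in {assembly, mapping-only, absent}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.cbs, columns=self.samples)

    def evidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.evidence, index=self.cbs, columns=self.samples)


def core_threshold(n_samples: int, core_fraction: float = 0.75) -> int:
    """Minimum sample count for core membership: ceil(fraction * n_samples)."""
    return math.ceil(core_fraction * n_samples)


def prevalence_and_core(
    calls: Sequence[DetectionCall],
    clusters: Sequence[SpeciesCluster],
    mags: Sequence[MAGRecord],
    core_fraction: float = 0.75,
) -> tuple[PrevalenceTable, list[str]]:
    """Presence matrix (assembly OR mapping) and the core CBS list.

    A cell is true when a member MAG of the CBS was assembled from that
    sample (evidence 'assembly') or the mapping rule fired there (evidence
    'mapping-only' when assembly evidence is missing). Core CBS are present
    in at least ceil(core_fraction * n_samples) samples.
    """
    samples = sorted({c.sample_id for c in calls})
    sample_ix = {s: i for i, s in enumerate(samples)}
    cbs_ids = [cl.cbs_id for cl in clusters]
    cbs_ix = {c: i for i, c in enumerate(cbs_ids)}
    mag_sample = {m.mag_id: m.sample_id for m in mags}

    evidence = np.full((len(cbs_ids), len(samples)), "absent", dtype=object)
    for cl in clusters:
        for mid in cl.member_mag_ids:
            s = mag_sample.get(mid)
            if s is None:
                raise ValueError(f"MAG {mid!r} missing from metadata")
            if s not in sample_ix:
                raise ValueError(
                    f"MAG {mid!r} originates from sample {s!r} outside the call universe"
                )
            evidence[cbs_ix[cl.cbs_id], sample_ix[s]] = "assembly"
    for call in calls:
        if call.cbs_id not in cbs_ix:
            raise ValueError(f"call references unknown CBS {call.cbs_id!r}")
        if call.present_by_mapping:
            i, j = cbs_ix[call.cbs_id], sample_ix[call.sample_id]
            if evidence[i, j] == "absent":
                evidence[i, j] = "mapping-only"
    cells = evidence != "absent"
    table = PrevalenceTable(samples, cbs_ids, cells, evidence)
    need = core_threshold(len(samples), core_fraction)
    counts = cells.sum(axis=1)
    core = [cbs_ids[i] for i in range(len(cbs_ids)) if counts[i] >= need]
    return table, core


@dataclass
class ConcordanceReport:
    """Agreement between mapping detections and screen confirmations."""

    n_detected: int
    n_confirmed: int
    fraction: float | None  # None when there are no detections
    unconfirmed_b2_strata: dict[str, int]


def concordance_report(
    calls: Sequence[DetectionCall],
    screens: Mapping[tuple[str, str], ScreenResult],
    min_containment: float = 0.95,
    max_pvalue: float = DEFAULT_MAX_PVALUE,
) -> ConcordanceReport:
    """Count detections, screen confirmations and the B2 strata of misses."""
    strata = {"0.5-0.7": 0, "0.7-0.9": 0, ">=0.9": 0}
    n_det = 0
    n_conf = 0
    for call in calls:
        if not call.present_by_mapping:
            continue
        n_det += 1
        key = (call.sample_id, call.cbs_id)
        if key not in screens:
            raise KeyError(f"no screen result for detection {key}")
        if confirm_with_screen(call, screens[key], min_containment, max_pvalue):
            n_conf += 1
        else:
            if call.b2 < 0.7:
                strata["0.5-0.7"] += 1
            elif call.b2 < 0.9:
                strata["0.7-0.9"] += 1
            else:
                strata[">=0.9"] += 1
    fraction = n_conf / n_det if n_det else None
    return ConcordanceReport(n_det, n_conf, fraction, strata)


def abundance_summary(
    fractions: Mapping[tuple[str, str], float],
    taxon_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-taxon summary of mapped-read percentages across (sample, CBS).

    Columns: median, q1, q3, iqr, mean, sd (all in percent) and n_cbs. Taxa
    with no CBS in ``fractions`` are omitted.
    """
    rows: dict[str, list[float]] = {}
    cbs_seen: dict[str, set[str]] = {}
    for (sample, cbs), frac in fractions.items():
        if cbs not in taxon_of:
            raise KeyError(f"CBS {cbs!r} missing from taxonomy")
        taxon = taxon_of[cbs]
        rows.setdefault(taxon, []).append(100.0 * frac)
        cbs_seen.setdefault(taxon, set()).add(cbs)
    records = []
    for taxon in sorted(rows):
        v = np.array(rows[taxon])
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        records.append(
            {
                "taxon": taxon,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(q3 - q1),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "n_cbs": len(cbs_seen[taxon]),
            }
        )
    return pd.DataFrame.from_records(records).set_index("taxon")


def read_mag_table(path) -> list[MAGRecord]:
    """Read MAG metadata TSV: mag_id, sample_id, completeness, contamination, n50."""
    df = pd.read_csv(path, sep="\t")
    required = {"mag_id", "sample_id", "completeness", "contamination", "n50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAG table missing columns: {sorted(missing)}")
    return [
        MAGRecord(
            str(r.mag_id),
            str(r.sample_id),
            float(r.completeness),
            float(r.contamination),
            int(r.n50),
        )
        for r in df.itertuples()
    ]
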