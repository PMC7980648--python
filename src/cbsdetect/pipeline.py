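"""End-to-end orchestration: simulate -> sketch -> map -> consensus -> detect.

``run_sample`` applies the whole per-sample detection procedure against a set
of CBS representatives; ``run_study`` additionally performs MAG
dereplication first and prevalence/core/abundance/concordance summaries
afterwards. All thresholds live in a single :class:`PipelineConfig` whose
defaults reproduce the published detection rule (B2 >= 0.5, ANI_CBS >= 0.95,
containment > 0.95, sketch size 10,000, core fraction 0.75).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import call_consensus, consensus_ani, pileup_counts
from .detect import (
    DEFAULT_MAX_PVALUE,
    ConcordanceReport,
    DetectionCall,
    MAGRecord,
    PrevalenceTable,
    SpeciesCluster,
    abundance_summary,
    concordance_report,
    confirm_with_screen,
    dereplicate,
    detect_presence,
    prevalence_and_core,
)
from .mapping import (
    ReferenceIndex,
    breadth_result,
    depth_profile,
    map_reads,
    mapped_fractions,
)
from .seqs import GenomeSequence
from .simulate import ReadSet
from .sketch import ReadKmerTable, ScreenResult, Sketch, build_sketch, screen

logger = logging.getLogger("cbsdetect")

__all__ = ["PipelineConfig", "SampleResult", "StudyResult", "run_sample", "run_study"]

REPORT_COLUMNS = [
    "sample",
    "cbs",
    "mapped_reads",
    "mapped_fraction",
    "mean_depth",
    "sd_depth",
    "q1_depth",
    "median_depth",
    "q3_depth",
    "ani_cbs",
    "B1",
    "B2",
    "B3",
    "B4",
    "B5",
    "containment",
    "shared_hashes",
    "median_multiplicity",
    "p_value",
    "present",
    "confirmed",
]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the detection pipeline.

    Defaults reproduce the published rule exactly; ``max_pvalue`` is a
    dataset-derived ceiling and therefore explicitly configurable.
    """

    k: int = 21
    sketch_size: int = 10000
    seed_length: int = 21
    max_mismatch_frac: float = 0.10
    frag_len: int = 1000
    min_frag_identity: float = 0.8
    b2_threshold: float = 0.5
    ani_threshold: float = 0.95
    derep_ani_threshold: float = 0.95
    min_containment: float = 0.95
    max_pvalue: float = DEFAULT_MAX_PVALUE
    core_fraction: float = 0.75
    depth_for_breadth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_mismatch_frac",
            "min_frag_identity",
            "b2_threshold",
            "ani_threshold",
            "derep_ani_threshold",
            "min_containment",
            "core_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.depth_for_breadth <= 5:
            raise ValueError("depth_for_breadth must be in 1..5")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SampleResult:
    sample_id: str
    calls: list[DetectionCall]
    screens: dict[tuple[str, str], ScreenResult]
    report: pd.DataFrame


@dataclass
class StudyResult:
    clusters: list[SpeciesCluster]
    calls: list[DetectionCall]
    screens: dict[tuple[str, str], ScreenResult]
    report: pd.DataFrame
    prevalence: PrevalenceTable
    core: list[str]
    concordance: ConcordanceReport
    abundance: pd.DataFrame | None = None


def run_sample(
    reads: ReadSet,
    representatives: Sequence[GenomeSequence],
    config: PipelineConfig | None = None,
    sketches: Mapping[str, Sketch] | None = None,
) -> SampleResult:
    """Full detection procedure for one sample against each representative.

    Per representative: align reads, compute the depth profile and breadth
    curve, call the masked consensus and its ANI to the representative,
    apply the presence rule, and screen-confirm detections. The read k-mer
    table and any provided sketches are shared across representatives.
    """
    if not representatives:
        raise ValueError("representatives must be non-empty")
    cfg = config or PipelineConfig()
    table = ReadKmerTable(reads, cfg.k)
    rows = []
    calls: list[DetectionCall] = []
    screens: dict[tuple[str, str], ScreenResult] = {}
    per_cbs: dict[str, dict] = {}
    counts: dict[str, int] = {}
    for rep in representatives:
        sk = sketches[rep.id] if sketches else build_sketch(rep, cfg.k, cfg.sketch_size)
        scr = screen(sk, table)
        index = ReferenceIndex(rep, cfg.seed_length)
        alignments = map_reads(
            reads, index, max_mismatch_frac=cfg.max_mismatch_frac
        )
        profile = depth_profile(alignments, rep)
        br = breadth_result(profile, mapped_reads=len(alignments))
        pile = pileup_counts(alignments, rep)
        cons = call_consensus(profile, pile, rep)
        ani = consensus_ani(
            cons, rep, frag_len=cfg.frag_len, min_frag_identity=cfg.min_frag_identity
        )
        ani_value = ani.ani if ani.defined else None
        b2 = br.breadth[cfg.depth_for_breadth]
        present = (
            b2 >= cfg.b2_threshold
            and ani_value is not None
            and ani_value >= cfg.ani_threshold
        )
        call = DetectionCall(
            sample_id=reads.sample_id,
            cbs_id=rep.id,
            b2=b2,
            ani_cbs=ani_value,
            present_by_mapping=present,
        )
        if present:
            call.confirmed_by_screen = confirm_with_screen(
                call, scr, cfg.min_containment, cfg.max_pvalue
            )
        calls.append(call)
        screens[(reads.sample_id, rep.id)] = scr
        counts[rep.id] = len(alignments)
        per_cbs[rep.id] = dict(br=br, ani=ani_value, scr=scr, call=call)
        logger.info(
            "sample=%s cbs=%s mapped=%d B2=%.4f ani=%s containment=%.4f present=%s",
            reads.sample_id,
            rep.id,
            len(alignments),
            b2,
            f"{ani_value:.4f}" if ani_value is not None else "NA",
            scr.containment,
            present,
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fractions = mapped_fractions(counts)
    for rep in representatives:
        d = per_cbs[rep.id]
        br, scr, call = d["br"], d["scr"], d["call"]
        rows.append(
            {
                "sample": reads.sample_id,
                "cbs": rep.id,
                "mapped_reads": br.mapped_reads,
                "mapped_fraction": fractions[rep.id],
                "mean_depth": br.mean_depth,
                "sd_depth": br.sd_depth,
                "q1_depth": br.q1,
                "median_depth": br.median_depth,
                "q3_depth": br.q3,
                "ani_cbs": d["ani"] if d["ani"] is not None else np.nan,
                "B1": br.breadth[1],
                "B2": br.breadth[2],
                "B3": br.breadth[3],
                "B4": br.breadth[4],
                "B5": br.breadth[5],
                "containment": scr.containment,
                "shared_hashes": scr.shared,
                "median_multiplicity": scr.median_multiplicity,
                "p_value": scr.p_value,
                "present": call.present_by_mapping,
                "confirmed": call.confirmed_by_screen,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return SampleResult(reads.sample_id, calls, screens, report)


def run_study(
    samples: Sequence[ReadSet],
    mags: Sequence[MAGRecord],
    genomes: Mapping[str, GenomeSequence],
    config: PipelineConfig | None = None,
    taxon_of: Mapping[str, str] | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Dereplicate, run every sample, then summarize the study.

    ``genomes`` maps MAG ids to sequences. Sample ids must be unique; the
    input order of samples does not affect any cell of the outputs.
    """
    cfg = config or PipelineConfig()
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if not samples:
        raise ValueError("at least one sample is required")
    usable = [m for m in mags if m.tier != "discarded"]
    clusters = dereplicate(
        usable,
        genomes,
        ani_threshold=cfg.derep_ani_threshold,
        frag_len=cfg.frag_len,
        min_frag_identity=cfg.min_frag_identity,
    )
    representatives = [
        GenomeSequence(cl.cbs_id, genomes[cl.representative_mag_id].seq)
        for cl in clusters
    ]
    sketches = {
        rep.id: build_sketch(rep, cfg.k, cfg.sketch_size) for rep in representatives
    }
    calls: list[DetectionCall] = []
    screens: dict[tuple[str, str], ScreenResult] = {}
    reports = []
    fractions: dict[tuple[str, str], float] = {}
    for sample in sorted(samples, key=lambda s: s.sample_id):
        res = run_sample(sample, representatives, cfg, sketches)
        calls.extend(res.calls)
        screens.update(res.screens)
        reports.append(res.report)
        for row in res.report.itertuples():
            fractions[(row.sample, row.cbs)] = row.mapped_fraction
    report = pd.concat(reports, ignore_index=True)

    # assembly evidence
    mag_cluster = {
        mid: cl.cbs_id for cl in clusters for mid in cl.member_mag_ids
    }
    mag_sample = {m.mag_id: m.sample_id for m in usable}
    assembled = {
        (mag_sample[mid], cbs) for mid, cbs in mag_cluster.items()
    }
    for call in calls:
        call.present_by_assembly = (call.sample_id, call.cbs_id) in assembled

    prevalence, core = prevalence_and_core(calls, clusters, usable, cfg.core_fraction)
    conc = concordance_report(calls, screens, cfg.min_containment, cfg.max_pvalue)
    abundance = (
        abundance_summary(fractions, taxon_of) if taxon_of is not None else None
    )
    result = StudyResult(
        clusters, calls, screens, report, prevalence, core, conc, abundance
    )
    if out_dir is not None:
        _write_study(result, cfg, Path(out_dir))
    return result


def _write_study(result: StudyResult, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out_dir / "config.json")
    result.report.to_csv(out_dir / "detection.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cbs_id": [c.cbs_id for c in result.clusters],
            "representative_mag_id": [c.representative_mag_id for c in result.clusters],
            "member_mag_ids": [",".join(c.member_mag_ids) for c in result.clusters],
        }
    ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    result.prevalence.to_frame().to_csv(out_dir / "prevalence.tsv", sep="\t")
    result.prevalence.evidence_frame().to_csv(out_dir / "evidence.tsv", sep="\t")
    (out_dir / "core.txt").write_text("\n".join(result.core) + "\n")
    if result.abundance is not None:
        result.abundance.to_csv(out_dir / "abundance.tsv", sep="\t")
    manifest = {
        "n_samples": len(result.prevalence.samples),
        "n_cbs": len(result.clusters),
        "n_detections": result.concordance.n_detected,
        "n_confirmed": result.concordance.n_confirmed,
        "confirmation_fraction": result.concordance.fraction,
        "core": result.core,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
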