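"""End-to-end orchestration: reads -> transcriptome alignment -> candidates
-> genome alignment -> breakpoints -> classified fusion table."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import alignment_io, breakpoint_engine, candidate_finder, classifier_reporter
from .reference_model import GenomeAnnotation, build_transcriptome, load_annotation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads: Optional[str] = None
    genome: Optional[str] = None
    annotation: Optional[str] = None
    transcriptome: Optional[str] = None
    transcriptome_paf: Optional[str] = None
    genome_paf: Optional[str] = None
    known_pairs: Optional[str] = None
    outdir: str = "."
    sample: str = "sample"
    # thresholds (defaults match the published method)
    max_overlap: int = 15
    max_gap: int = 15
    min_seg_len: int = 0
    intron_filter: int = 10_000
    anchor_window: int = 20
    consistency_tol: int = 10
    cluster_radius: float = 50.0
    readthrough_dist: int = 200_000
    mito_names: tuple[str, ...] = ("chrM", "MT")
    mito_filter: bool = True
    keep_readthrough: bool = False
    aligner: str = "minimap2"
    threads: int = 1

    def __post_init__(self):
        for name in ("max_overlap", "max_gap", "intron_filter", "anchor_window",
                     "consistency_tol", "cluster_radius", "readthrough_dist"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "mito_names" in data:
            data["mito_names"] = tuple(data["mito_names"])
        return cls(**data)


@dataclass
class PipelineResult:
    calls_df: pd.DataFrame
    filtered_df: pd.DataFrame
    multifusion_df: pd.DataFrame
    counts: dict
    candidate_read_ids: set[str]
    calls: list = field(default_factory=list)
    breakpoints: list = field(default_factory=list)


def _load_read_seqs(path) -> dict[str, str]:
    from Bio import SeqIO
    fmt = "fastq" if _looks_fastq(path) else "fasta"
    with alignment_io._open_maybe_gzip(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, fmt)}


def _looks_fastq(path) -> bool:
    with alignment_io._open_maybe_gzip(path) as fh:
        first = fh.read(1)
    return first == "@"


def _genome_accessor(genome_fa):
    from pyfaidx import Fasta
    return Fasta(str(genome_fa))


def run_call(cfg: PipelineConfig, ann: Optional[GenomeAnnotation] = None
             ) -> PipelineResult:
    """Execute the five pipeline stages and write the output tables.

    Either an aligner binary must be available or pre-computed PAF files must
    be supplied for both stages. Stage counts are logged and returned.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ann is None:
        ann = load_annotation(cfg.annotation, mito_names=cfg.mito_names)

    read_seqs = _load_read_seqs(cfg.reads) if cfg.reads else {}
    counts: dict = {"reads_in": len(read_seqs)}

    # stage 1: transcriptome alignment
    tx_paf = cfg.transcriptome_paf
    if tx_paf is None:
        tx_fa = cfg.transcriptome
        if tx_fa is None:
            tx_fa = outdir / "transcriptome.fa"
            build_transcriptome(ann, _genome_accessor(cfg.genome), out_fasta=tx_fa)
        reads_fa = outdir / "reads.fa"
        if cfg.reads and _looks_fastq(cfg.reads):
            alignment_io.convert_fastq_to_fasta(cfg.reads, reads_fa)
        else:
            reads_fa = cfg.reads
        tx_paf = outdir / "transcriptome.paf"
        alignment_io.run_aligner("transcriptome", tx_fa, reads_fa, tx_paf,
                                 binary=cfg.aligner, threads=cfg.threads)

    # transcript -> gene map accepting both "txid" and "txid|gene" target names
    target2gene = dict(ann.tx2gene)
    for tx_id, gene in ann.tx2gene.items():
        target2gene[f"{tx_id}|{gene}"] = gene

    segments = list(alignment_io.read_paf(tx_paf))
    counts["reads_aligned_tx"] = len({s.read_id for s in segments})

    # stage 2: candidate selection
    candidates = list(candidate_finder.find_candidates(
        alignment_io.group_by_read(segments), target2gene,
        max_overlap=cfg.max_overlap, max_gap=cfg.max_gap,
        min_seg_len=cfg.min_seg_len))
    counts["candidate_reads"] = len(candidates)
    candidate_ids = {c.read_id for c in candidates}
    preferred = {c.read_id: set(c.genes) for c in candidates}
    candidate_finder.write_candidate_tsv(candidates, outdir / "candidates.tsv")

    # stage 3: genome alignment of candidate reads
    genome_paf = cfg.genome_paf
    if genome_paf is None:
        cand_fa = outdir / "candidates.fa"
        candidate_finder.write_candidate_fasta(candidates, read_seqs, cand_fa)
        genome_paf = outdir / "genome.paf"
        if candidates:
            alignment_io.run_aligner("genome", cfg.genome, cand_fa, genome_paf,
                                     binary=cfg.aligner, threads=cfg.threads)
        else:
            Path(genome_paf).write_text("")

    genome_reads = [r for r in alignment_io.group_by_read(
        alignment_io.read_paf(genome_paf)) if r.read_id in candidate_ids
        or not candidate_ids]

    # stage 4: breakpoints
    raws = breakpoint_engine.extract_raw_breakpoints(genome_reads, ann,
                                                     preferred_genes=preferred)
    counts["genome_confirmed_reads"] = len({r.read_id for r in raws})
    raws = breakpoint_engine.filter_regular_transcription(
        raws, max_dist=cfg.intron_filter)
    counts["raw_breakpoints_post_intron_filter"] = len(raws)
    per_raw = [breakpoint_engine.anchor_to_exons(
        r, ann, window=cfg.anchor_window, consistency_tol=cfg.consistency_tol)
        for r in raws]
    per_read_junctions: dict[str, list] = {}
    for r, c in zip(raws, per_raw):
        per_read_junctions.setdefault(r.read_id, []).append(
            replace(r, pos5=c.pos5, pos3=c.pos3))
    cands = breakpoint_engine.aggregate_candidates(per_raw)
    bps = breakpoint_engine.cluster_breakpoints(cands, radius=cfg.cluster_radius)
    counts["breakpoints"] = len(bps)

    # stage 5: classify, filter, annotate, rank, report
    calls, discarded = classifier_reporter.classify_all(bps)
    for cls in ("HighConfidence", "LowConfidence", "PotentialTransSplicing"):
        counts[f"class_{cls}"] = sum(c.classification == cls for c in calls)
    counts["discarded_singleton_non_boundary"] = len(discarded)
    calls = classifier_reporter.filter_read_through(
        calls, max_dist=cfg.readthrough_dist)
    calls = classifier_reporter.filter_mitochondrial(
        calls, ann, enabled=cfg.mito_filter)
    counts["filtered_read_through"] = sum(
        c.filtered_reason == "read_through" for c in calls)
    counts["filtered_mitochondrial"] = sum(
        c.filtered_reason == "mitochondrial" for c in calls)
    known = (classifier_reporter.load_known_pairs(cfg.known_pairs)
             if cfg.known_pairs else set())
    for c in calls:
        classifier_reporter.annotate_frame(c, ann)
        classifier_reporter.annotate_known(c, known)

    calls_df = classifier_reporter.rank_and_report(
        calls, outdir / "fusions.csv", sample=cfg.sample,
        keep_readthrough=cfg.keep_readthrough)
    filtered_df = classifier_reporter.report_filtered(
        calls, outdir / "fusions_filtered.csv", sample=cfg.sample)
    events = classifier_reporter.detect_multifusions(
        per_read_junctions, calls, radius=cfg.cluster_radius)
    multi_df = classifier_reporter.multifusions_to_frame(events)
    multi_df.to_csv(outdir / "multifusions.csv", index=False)
    counts["reported_calls"] = len(calls_df)
    with open(outdir / "stage_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)
    for k, v in counts.items():
        logger.info("stage count %s = %s", k, v)
    return PipelineResult(calls_df=calls_df, filtered_df=filtered_df,
                          multifusion_df=multi_df, counts=counts,
                          candidate_read_ids=candidate_ids, calls=calls,
                          breakpoints=bps)


def run_simulate(outdir, seed: int = 0, n_fusions: int = 20,
                 coverages=(10,), identities=(95.0,),
                 n_background: int = 0, n_artifacts: int = 0,
                 sim_overrides: Optional[dict] = None) -> dict:
    """Generate a reference, fusion/artifact transcripts and reads on disk."""
    from . import simulator
    from .reference_model import write_gtf
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_genes = max(40, 2 * n_fusions + 2 * n_artifacts + n_background + 10)
    overrides = dict(sim_overrides or {})
    overrides.setdefault("n_chroms", max(6, -(-n_genes // 80)))
    cfg = simulator.SimConfig(n_genes=n_genes, n_fusions=n_fusions,
                              coverages=tuple(coverages),
                              identities=tuple(identities), seed=seed,
                              **overrides)
    rng = cfg.rng()
    genome, ann = simulator.generate_reference(cfg, rng)
    genes = sorted(ann.genes_by_key)
    fusions = simulator.make_fusion_transcripts(ann, genome, cfg, rng)
    fusion_genes = {g for t in fusions for g in (t.gene5, t.gene3)}
    spare = [g for g in genes if g not in fusion_genes]
    truths = simulator.assign_grid(fusions, cfg.coverages, cfg.identities)
    if n_artifacts:
        arts = simulator.make_chimeric_artifacts(
            ann, genome, n_artifacts, cfg, rng, gene_pool=spare[:2 * n_artifacts])
        spare = spare[2 * n_artifacts:]
        truths += simulator.assign_grid(arts, cfg.coverages, cfg.identities)
    if n_background:
        bg = simulator.make_background_transcripts(ann, genome,
                                                   spare[:n_background])
        truths += simulator.assign_grid(bg, cfg.coverages, cfg.identities)
    reads = simulator.simulate_reads(truths, cfg, rng,
                                     fastq_path=outdir / "reads.fastq")
    simulator.write_genome_fasta(genome, outdir / "genome.fa")
    write_gtf(ann, outdir / "annotation.gtf")
    simulator.write_truth_tsv(truths, outdir / "truth.tsv")
    simulator.write_read_truth_tsv(reads, outdir / "read_truth.tsv")
    return {"config": dataclasses.asdict(cfg), "n_reads": len(reads),
            "genome": str(outdir / "genome.fa"),
            "annotation": str(outdir / "annotation.gtf"),
            "reads": str(outdir / "reads.fastq"),
            "truth": str(outdir / "truth.tsv"),
            "read_truth": str(outdir / "read_truth.tsv")}


def run_evaluate(calls_csv, truth_tsv, outdir, radius: float = 1000.0) -> dict:
    """Match calls to truth, write the sensitivity grid and a summary JSON."""
    from . import evaluator
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = evaluator.load_calls_csv(calls_csv)
    truth = evaluator.load_truth_tsv(truth_tsv)
    truth = truth[truth.category != "normal"].reset_index(drop=True)
    matches = evaluator.match_truth(calls, truth, radius=radius)
    grid, summary = evaluator.sensitivity_grid(matches, truth)
    recovery = evaluator.support_recovery(matches, calls, truth)
    grid.to_csv(outdir / "sensitivity_grid.tsv", sep="\t")
    summary["support_recovery_by_identity"] = {
        str(k): float(v) for k, v in recovery.items()}
    with open(outdir / "evaluation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
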