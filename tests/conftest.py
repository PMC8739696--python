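"""Shared fixtures: tiny hand-built annotations and small end-to-end runs."""

from __future__ import annotations

import pytest

from longfuse.reference_model import Exon, GenomeAnnotation, TranscriptModel


def make_transcript(tx_id, gene, chrom, strand, exons, cds=(), gene_name=None):
    ex = [Exon(chrom, s, e, strand) for s, e in exons]
    if strand == "-":
        ex = sorted(ex, key=lambda e: e.start, reverse=True)
    return TranscriptModel(transcript_id=tx_id, gene_id=gene,
                           gene_name=gene_name if gene_name is not None else gene,
                           exons=tuple(ex), cds_intervals=tuple(sorted(cds)))


@pytest.fixture
def toy_ann():
    """Three genes: two plus-strand on chr1/chr2 (with CDS), one minus-strand."""
    txs = {
        "tA": make_transcript("tA", "geneA", "chr1", "+",
                              [(1000, 1400), (2000, 2400), (3000, 3400)],
                              cds=[(1100, 1400), (2000, 2400), (3000, 3100)]),
        "tB": make_transcript("tB", "geneB", "chr2", "+",
                              [(90000, 90500), (91000, 91600)],
                              cds=[(90000, 90500), (91000, 91300)]),
        "tC": make_transcript("tC", "geneC", "chr1", "-",
                              [(50000, 50300), (51000, 51400)]),
    }
    return GenomeAnnotation(txs)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """End-to-end run on 5 simulated fusions at coverage 10, identity 95."""
    import pandas as pd
    from longfuse.pipeline import PipelineConfig, run_call, run_simulate
    work = tmp_path_factory.mktemp("small_study")
    sim = run_simulate(work / "sim", seed=7, n_fusions=5, coverages=(10,),
                       identities=(95.0,))
    cfg = PipelineConfig(reads=sim["reads"], genome=sim["genome"],
                         annotation=sim["annotation"], outdir=str(work / "call"))
    result = run_call(cfg)
    truth = pd.read_csv(sim["truth"], sep="\t")
    return {"sim": sim, "cfg": cfg, "result": result, "truth": truth,
            "workdir": work}


@pytest.fixture(scope="session")
def negative_study(tmp_path_factory):
    """End-to-end run on non-fusion background reads only."""
    from longfuse.pipeline import PipelineConfig, run_call, run_simulate
    work = tmp_path_factory.mktemp("negative_study")
    sim = run_simulate(work / "sim", seed=11, n_fusions=0, coverages=(10,),
                       identities=(90.0,), n_background=25)
    cfg = PipelineConfig(reads=sim["reads"], genome=sim["genome"],
                         annotation=sim["annotation"], outdir=str(work / "call"))
    return {"sim": sim, "result": run_call(cfg)}
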