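"""Synthetic references, fusion transcripts, noisy long reads, and chimera
artifacts.

The generator emulates the ingredients of a long-read fusion benchmark at
desk scale: a small multi-chromosome genome carrying non-overlapping
multi-exon gene models (introns get GT..AG splice dinucleotides so a spliced
aligner behaves as on real genomes), fusion transcripts built by joining a
randomly selected exon of one gene to a randomly selected exon of another
(at least 100 bp of sequence from each side), full-length reads with a
per-read identity drawn from Normal(mean, 5) truncated to (50, 100] and
errors applied as substitutions/insertions/deletions in a 1:1:1 ratio, and
library-preparation chimera artifacts whose junctions fall inside exon
bodies (>=25 bp from every boundary).

All randomness flows from the config seed; outputs are byte-identical across
runs with the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .reference_model import (Exon, GenomeAnnotation, TranscriptModel,
                              reverse_complement, transcript_sequence)

DEFAULT_COVERAGES = (1, 2, 10, 50, 100)
DEFAULT_IDENTITIES = (75, 80, 85, 90, 95)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


@dataclass
class SimConfig:
    n_genes: int = 120
    n_chroms: int = 6
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 2000)
    intergenic_gap: tuple[int, int] = (1000, 4000)
    utr_stub: tuple[int, int] = (20, 60)
    n_fusions: int = 20
    coverages: tuple[int, ...] = DEFAULT_COVERAGES
    identities: tuple[float, ...] = DEFAULT_IDENTITIES
    identity_sd: float = 5.0
    min_side: int = 100
    artifact_boundary_margin: int = 25
    revcomp_fraction: float = 0.5
    # optional read truncation: keep a contiguous U(lo, hi) fraction of each
    # read at a random offset (off by default: reads are full length)
    truncation: Optional[tuple[float, float]] = None
    include_mito: bool = False
    seed: int = 0

    def __post_init__(self):
        if not all(50 < i <= 100 for i in self.identities):
            raise ValueError("identities must lie in (50, 100]")
        if self.min_side < 1:
            raise ValueError("min_side must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FusionTruth:
    """One simulated transcript (true fusion, chimera artifact, or a plain
    background transcript) with its genomic junction and read parameters."""

    fusion_id: str
    category: str  # fusion | artifact | normal
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    seq: str
    coverage: int = 0
    identity: float = 95.0


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _rand_int(rng, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _make_gene_model(rng, cfg: SimConfig, chrom: str, offset: int,
                     gene_idx: int) -> tuple[TranscriptModel, int]:
    """One gene with a single transcript; returns (model, end_of_span)."""
    n_exons = _rand_int(rng, cfg.exons_per_gene)
    strand = "+" if rng.random() < 0.5 else "-"
    pos = offset
    genomic_exons: list[tuple[int, int]] = []
    for i in range(n_exons):
        elen = _rand_int(rng, cfg.exon_length)
        genomic_exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += _rand_int(rng, cfg.intron_length)
    gene_id = f"G{gene_idx:04d}"
    exons = [Exon(chrom, s, e, strand) for s, e in genomic_exons]
    if strand == "-":
        exons = exons[::-1]
    # CDS: whole transcript minus short terminal UTR stubs, trimmed to a
    # multiple of three so frame annotation is meaningful
    tx_len = sum(e - s for s, e in genomic_exons)
    utr5 = _rand_int(rng, cfg.utr_stub)
    utr3 = _rand_int(rng, cfg.utr_stub)
    cds_len = max(0, tx_len - utr5 - utr3)
    cds_len -= cds_len % 3
    cds = _tx_interval_to_genomic(exons, utr5, utr5 + cds_len) if cds_len >= 3 else ()
    tx = TranscriptModel(transcript_id=f"T{gene_idx:04d}", gene_id=gene_id,
                         gene_name=f"GENE{gene_idx:04d}", exons=tuple(exons),
                         cds_intervals=tuple(cds))
    return tx, pos


def _tx_interval_to_genomic(exons_tx_order: Sequence[Exon], tx_start: int,
                            tx_end: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic intervals."""
    out = []
    cum = 0
    for e in exons_tx_order:
        elen = len(e)
        lo = max(tx_start, cum)
        hi = min(tx_end, cum + elen)
        if lo < hi:
            o1, o2 = lo - cum, hi - cum
            if e.strand == "+":
                out.append((e.start + o1, e.start + o2))
            else:
                out.append((e.end - o2, e.end - o1))
        cum += elen
    return sorted(out)


def generate_reference(cfg: SimConfig, rng: Optional[np.random.Generator] = None
                       ) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random multi-chromosome genome plus indexed annotation."""
    rng = cfg.rng() if rng is None else rng
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    transcripts: dict[str, TranscriptModel] = {}
    chrom_len: dict[str, int] = {}
    gene_idx = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = _rand_int(rng, cfg.intergenic_gap)
        for _ in range(n_here):
            tx, end = _make_gene_model(rng, cfg, chrom, pos, gene_idx)
            transcripts[tx.transcript_id] = tx
            gene_idx += 1
            pos = end + _rand_int(rng, cfg.intergenic_gap)
        chrom_len[chrom] = pos
    if cfg.include_mito:
        chrom = "chrM"
        pos = 200
        for _ in range(2):
            tx, end = _make_gene_model(rng, cfg, chrom, pos, gene_idx)
            transcripts[tx.transcript_id] = tx
            gene_idx += 1
            pos = end + 300
        chrom_len[chrom] = pos
    genome: dict[str, str] = {}
    for chrom, length in chrom_len.items():
        arr = _BASES[rng.integers(0, 4, size=length)]
        genome[chrom] = arr.tobytes().decode()
    _plant_splice_sites(genome, transcripts)
    return genome, GenomeAnnotation(transcripts)


def _plant_splice_sites(genome: dict[str, str], transcripts) -> None:
    """Overwrite intron edges with GT..AG (strand-aware) so spliced aligners
    see canonical splice signals."""
    arrays = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for tx in transcripts.values():
        ex = sorted(tx.exons, key=lambda e: e.start)
        arr = arrays[tx.chrom]
        for a, b in zip(ex, ex[1:]):
            if tx.strand == "+":
                arr[a.end:a.end + 2] = b"GT"
                arr[b.start - 2:b.start] = b"AG"
            else:
                arr[a.end:a.end + 2] = b"CT"
                arr[b.start - 2:b.start] = b"AC"
    for c in genome:
        genome[c] = arrays[c].decode()


def write_genome_fasta(genome: dict[str, str], path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), line_width):
                fh.write(s[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Fusion and artifact transcripts
# ---------------------------------------------------------------------------

def _prefix_cut_choices(tx: TranscriptModel, min_side: int) -> list[int]:
    """Exon indices k (transcription order) where the prefix through exon k
    is >= min_side and the cut is not the transcript end."""
    cum = 0
    out = []
    for k, e in enumerate(tx.exons):
        cum += len(e)
        if cum >= min_side and k < len(tx.exons) - 1:
            out.append(k)
    return out


def _suffix_cut_choices(tx: TranscriptModel, min_side: int) -> list[int]:
    total = tx.spliced_length
    cum = 0
    out = []
    for j, e in enumerate(tx.exons):
        if j > 0 and total - cum >= min_side:
            out.append(j)
        cum += len(e)
    return out


def _donor_cut(e: Exon) -> int:
    return e.end if e.strand == "+" else e.start


def _acceptor_cut(e: Exon) -> int:
    return e.start if e.strand == "+" else e.end


def make_fusion_transcripts(ann: GenomeAnnotation, genome, cfg: SimConfig,
                            rng: Optional[np.random.Generator] = None,
                            n_fusions: Optional[int] = None,
                            gene_pool: Optional[Sequence[str]] = None
                            ) -> list[FusionTruth]:
    """Exon-join fusion transcripts between genes on different chromosomes.

    Each fusion joins the 5' gene's transcript prefix ending at a randomly
    selected exon boundary to the 3' gene's suffix starting at a randomly
    selected exon, with at least ``cfg.min_side`` bases from each gene.
    Genes are sampled without replacement across fusions.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_fusions if n_fusions is None else n_fusions
    pool = list(gene_pool) if gene_pool is not None else sorted(ann.genes_by_key)
    usable = [g for g in pool
              if _prefix_cut_choices(_first_tx(ann, g), cfg.min_side)
              and _suffix_cut_choices(_first_tx(ann, g), cfg.min_side)]
    if len(usable) < 2 * n:
        raise ValueError(f"need {2 * n} usable genes, have {len(usable)}")
    order = list(rng.permutation(len(usable)))
    picked: list[tuple[str, str]] = []
    remaining = [usable[i] for i in order]
    for _ in range(n):
        g5 = remaining.pop(0)
        c5 = ann.gene(g5).chrom
        j = next((i for i, g in enumerate(remaining) if ann.gene(g).chrom != c5),
                 None)
        if j is None:
            raise ValueError("cannot pair remaining genes across chromosomes")
        picked.append((g5, remaining.pop(j)))
    out: list[FusionTruth] = []
    for idx, (g5, g3) in enumerate(picked):
        tx5, tx3 = _first_tx(ann, g5), _first_tx(ann, g3)
        k = int(rng.choice(_prefix_cut_choices(tx5, cfg.min_side)))
        j = int(rng.choice(_suffix_cut_choices(tx3, cfg.min_side)))
        seq5 = transcript_sequence(tx5, genome)
        seq3 = transcript_sequence(tx3, genome)
        pre_len = sum(len(e) for e in tx5.exons[:k + 1])
        suf_off = sum(len(e) for e in tx3.exons[:j])
        out.append(FusionTruth(
            fusion_id=f"F{idx:04d}", category="fusion",
            gene5=g5, gene3=g3,
            chrom5=tx5.chrom, pos5=_donor_cut(tx5.exons[k]), strand5=tx5.strand,
            chrom3=tx3.chrom, pos3=_acceptor_cut(tx3.exons[j]), strand3=tx3.strand,
            seq=seq5[:pre_len] + seq3[suf_off:]))
    return out


def _first_tx(ann: GenomeAnnotation, gene_key: str) -> TranscriptModel:
    return ann.transcripts[sorted(ann.gene(gene_key).transcript_ids)[0]]


def make_chimeric_artifacts(ann: GenomeAnnotation, genome, n: int,
                            cfg: SimConfig,
                            rng: Optional[np.random.Generator] = None,
                            gene_pool: Optional[Sequence[str]] = None
                            ) -> list[FusionTruth]:
    """Library-prep chimera stand-ins: join a random intra-exon position of
    one transcript to a random intra-exon position of another (each cut at
    least ``artifact_boundary_margin`` bp from every exon boundary, no
    adapter between the parts)."""
    rng = cfg.rng() if rng is None else rng
    margin = cfg.artifact_boundary_margin
    pool = list(gene_pool) if gene_pool is not None else sorted(ann.genes_by_key)
    out: list[FusionTruth] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * n:
            raise RuntimeError("could not place chimera artifacts; exons too short")
        i5, i3 = rng.choice(len(pool), size=2, replace=False)
        g5, g3 = pool[int(i5)], pool[int(i3)]
        tx5, tx3 = _first_tx(ann, g5), _first_tx(ann, g3)
        cut5 = _intra_exon_cut(tx5, rng, margin, cfg.min_side, prefix=True)
        cut3 = _intra_exon_cut(tx3, rng, margin, cfg.min_side, prefix=False)
        if cut5 is None or cut3 is None:
            continue
        tpos5, gpos5 = cut5
        tpos3, gpos3 = cut3
        seq5 = transcript_sequence(tx5, genome)
        seq3 = transcript_sequence(tx3, genome)
        out.append(FusionTruth(
            fusion_id=f"A{len(out):04d}", category="artifact",
            gene5=g5, gene3=g3,
            chrom5=tx5.chrom, pos5=gpos5, strand5=tx5.strand,
            chrom3=tx3.chrom, pos3=gpos3, strand3=tx3.strand,
            seq=seq5[:tpos5] + seq3[tpos3:]))
    return out


def _intra_exon_cut(tx: TranscriptModel, rng, margin: int, min_side: int,
                    prefix: bool) -> Optional[tuple[int, int]]:
    """Pick a transcript cut inside an exon body; returns (tx_pos, genome_pos)."""
    choices = []
    cum = 0
    total = tx.spliced_length
    for e in tx.exons:
        lo, hi = margin, len(e) - margin
        if hi > lo:
            choices.append((cum, e, lo, hi))
        cum += len(e)
    rng.shuffle(choices)
    for cum, e, lo, hi in choices:
        off = int(rng.integers(lo, hi))
        tx_pos = cum + off
        side_len = tx_pos if prefix else total - tx_pos
        if side_len < min_side:
            continue
        gpos = e.start + off if e.strand == "+" else e.end - off
        return tx_pos, gpos
    return None


def make_background_transcripts(ann: GenomeAnnotation, genome,
                                gene_pool: Sequence[str]) -> list[FusionTruth]:
    """Plain (non-fusion) transcripts, for background reads and negative
    controls."""
    out = []
    for i, g in enumerate(gene_pool):
        tx = _first_tx(ann, g)
        out.append(FusionTruth(
            fusion_id=f"N{i:04d}", category="normal",
            gene5=g, gene3=g, chrom5=tx.chrom, pos5=-1, strand5=tx.strand,
            chrom3=tx.chrom, pos3=-1, strand3=tx.strand,
            seq=transcript_sequence(tx, genome)))
    return out


def assign_grid(truths: list[FusionTruth], coverages: Sequence[int],
                identities: Sequence[float]) -> list[FusionTruth]:
    """Assign (coverage, identity) cells round-robin across truths, so each
    cell receives len(truths) / (len(coverages) * len(identities)) fusions."""
    cells = [(c, i) for i in identities for c in coverages]
    out = []
    for idx, t in enumerate(truths):
        cov, ident = cells[idx % len(cells)]
        out.append(replace(t, coverage=cov, identity=ident))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def add_read_noise(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply substitution/insertion/deletion errors (1:1:1) at the given
    per-base rate."""
    if error_rate <= 0 or not seq:
        return seq
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    err = rng.random(n) < error_rate
    etype = rng.integers(0, 3, size=n)
    sub = err & (etype == 0)
    dele = err & (etype == 1)
    ins = err & (etype == 2)
    mod = codes.copy()
    if sub.any():
        mod[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    out = np.repeat(mod, counts)
    if ins.any():
        starts = np.cumsum(counts) - counts
        out[starts[ins] + 1] = rng.integers(0, 4, size=int(ins.sum()))
    return _BASES[out].tobytes().decode()


def simulate_reads(truths: Iterable[FusionTruth], cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   fastq_path=None) -> list[tuple[str, str, str]]:
    """Full-length reads per transcript: ceil(coverage) reads each, per-read
    identity ~ Normal(assigned identity, cfg.identity_sd) truncated to
    (50, 100], half the reads reverse-complemented.

    Returns [(read_id, fusion_id, sequence)]; read ids encode the source
    transcript for truth matching.
    """
    rng = cfg.rng() if rng is None else rng
    reads: list[tuple[str, str, str]] = []
    for t in truths:
        n_reads = max(0, math.ceil(t.coverage))
        idents = np.clip(rng.normal(t.identity, cfg.identity_sd, size=n_reads),
                         50.0 + 1e-9, 100.0)
        for i in range(n_reads):
            tmpl = t.seq
            if cfg.truncation is not None:
                lo, hi = cfg.truncation
                keep = max(1, round(len(tmpl) * rng.uniform(lo, hi)))
                off = int(rng.integers(0, len(tmpl) - keep + 1))
                tmpl = tmpl[off:off + keep]
            seq = add_read_noise(tmpl, 1.0 - idents[i] / 100.0, rng)
            if rng.random() < cfg.revcomp_fraction:
                seq = reverse_complement(seq)
            reads.append((f"{t.fusion_id}_r{i:04d}", t.fusion_id, seq))
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for read_id, _fid, seq in reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return reads


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["fusion_id", "category", "gene5", "gene3", "chrom5", "base5",
                 "strand5", "chrom3", "base3", "strand3", "coverage", "identity"]


def write_truth_tsv(truths: Iterable[FusionTruth], path) -> None:
    """Fusion-level truth; positions 1-based, matching the calls CSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write("\t".join(map(str, [
                t.fusion_id, t.category, t.gene5, t.gene3,
                t.chrom5, t.pos5 + 1, t.strand5,
                t.chrom3, t.pos3 + 1, t.strand3,
                t.coverage, t.identity])) + "\n")


def write_read_truth_tsv(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tfusion_id\n")
        for read_id, fid, _seq in reads:
            fh.write(f"{read_id}\t{fid}\n")
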