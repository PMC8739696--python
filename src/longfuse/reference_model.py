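"""Gene annotation model: GTF loading, transcriptome building, exon-boundary queries.

All internal coordinates are 0-based half-open; breakpoints live in the same
space as exon ``start``/``end`` values (inter-base cut points). Conversions to
and from 1-based conventions happen only at the GTF and CSV edges.
"""

from __future__ import annotations

import logging
import re
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise AnnotationError(f"exon start {self.start} !< end {self.end}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """A transcript: exons kept in transcription order (5' -> 3' of the mRNA)."""

    transcript_id: str
    gene_id: str
    gene_name: str
    exons: tuple[Exon, ...]
    cds_intervals: tuple[tuple[int, int], ...] = ()

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        """Gene identity used for fusion calling: name when present, else id."""
        return self.gene_name or self.gene_id


class GenomeAnnotation:
    """Indexed gene annotation.

    Holds transcripts and genes, a transcript -> gene-identity map, per-gene
    sorted exon-boundary indices (positions tagged ``start``/``end``), and a
    per-chromosome interval tree of gene spans for genome-alignment gene
    assignment.
    """

    def __init__(self, transcripts: Mapping[str, TranscriptModel],
                 mito_names: Iterable[str] = DEFAULT_MITO_NAMES):
        self.transcripts: dict[str, TranscriptModel] = dict(transcripts)
        self.mito_names = frozenset(mito_names)
        self.genes: dict[str, GeneModel] = {}
        self.tx2gene: dict[str, str] = {}
        for tx in self.transcripts.values():
            span = tx.span
            g = self.genes.get(tx.gene_id)
            if g is None:
                g = GeneModel(tx.gene_id, tx.gene_name, tx.chrom, tx.strand,
                              span[0], span[1])
                self.genes[tx.gene_id] = g
            else:
                g.start = min(g.start, span[0])
                g.end = max(g.end, span[1])
            g.transcript_ids.append(tx.transcript_id)
            self.tx2gene[tx.transcript_id] = g.key
        # gene identity key -> GeneModel (key may equal gene_id)
        self.genes_by_key: dict[str, GeneModel] = {g.key: g for g in self.genes.values()}
        self._build_boundary_index()
        self._build_gene_trees()

    def _build_boundary_index(self):
        # per gene key: parallel sorted lists of boundary positions and sides
        by_gene: dict[str, set[tuple[int, str]]] = {}
        for tx in self.transcripts.values():
            key = self.tx2gene[tx.transcript_id]
            s = by_gene.setdefault(key, set())
            for e in tx.exons:
                s.add((e.start, "start"))
                s.add((e.end, "end"))
        self._boundaries: dict[str, list[tuple[int, str]]] = {
            k: sorted(v) for k, v in by_gene.items()
        }
        self._boundary_pos: dict[str, list[int]] = {
            k: [p for p, _ in v] for k, v in self._boundaries.items()
        }

    def _build_gene_trees(self):
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._gene_trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end, g.key)

    # -- queries ---------------------------------------------------------

    def gene(self, key: str) -> GeneModel:
        try:
            return self.genes_by_key[key]
        except KeyError:
            raise AnnotationError(f"unknown gene {key!r}") from None

    def boundaries_near(self, gene_key: str, chrom: str, pos: int,
                        window: int) -> list[tuple[int, str]]:
        """Exon boundaries of ``gene_key`` within ``window`` bp of ``pos``.

        Returns (boundary_position, side) sorted by distance then position;
        side is ``"start"`` or ``"end"``. Boundaries shared between
        transcripts are reported once per side.
        """
        if window < 0:
            raise ValueError("window must be >= 0")
        g = self.gene(gene_key)
        if g.chrom != chrom:
            return []
        entries = self._boundaries.get(gene_key, [])
        positions = self._boundary_pos.get(gene_key, [])
        lo = bisect_left(positions, pos - window)
        hi = bisect_right(positions, pos + window)
        hits = entries[lo:hi]
        return sorted(hits, key=lambda bp: (abs(bp[0] - pos), bp[0], bp[1]))

    def boundary_set(self, gene_key: str, side: Optional[str] = None) -> set[int]:
        return {p for p, s in self._boundaries.get(gene_key, ())
                if side is None or s == side}

    def genes_overlapping(self, chrom: str, intervals: Sequence[tuple[int, int]]
                          ) -> dict[str, int]:
        """Gene keys overlapping any of the intervals, with total overlap bp."""
        tree = self._gene_trees.get(chrom)
        out: dict[str, int] = {}
        if tree is None:
            return out
        for s, e in intervals:
            for iv in tree.overlap(s, e):
                ov = min(e, iv.end) - max(s, iv.begin)
                if ov > 0:
                    out[iv.data] = out.get(iv.data, 0) + ov
        return out

    def is_mito(self, chrom: str) -> bool:
        return chrom in self.mito_names

    # -- coding frame ----------------------------------------------------

    def _coding_blocks(self, tx: TranscriptModel) -> list[tuple[int, int]]:
        """CDS intervals in transcription order."""
        blocks = sorted(tx.cds_intervals)
        if tx.strand == "-":
            blocks = blocks[::-1]
        return blocks

    def coding_prefix_length(self, transcript_id: str, genomic_pos: int,
                             side: str = "up_to") -> Optional[int]:
        """Coding bases between the CDS start (or end) and a breakpoint.

        ``genomic_pos`` is a cut point. ``side="up_to"`` counts coding bases
        from the CDS start to the cut along the transcript; ``side="from"``
        counts from the cut to the CDS end. Returns None when the transcript
        has no CDS or the cut lies outside the CDS span.
        """
        tx = self.transcripts.get(transcript_id)
        if tx is None:
            raise AnnotationError(f"unknown transcript {transcript_id!r}")
        if not tx.cds_intervals:
            return None
        blocks = self._coding_blocks(tx)
        total = sum(e - s for s, e in blocks)
        plus = tx.strand == "+"
        prefix = 0
        inside = False
        for s, e in blocks:
            if plus:
                if s <= genomic_pos <= e:
                    prefix += genomic_pos - s
                    inside = True
                    break
                prefix += e - s
            else:
                if s <= genomic_pos <= e:
                    prefix += e - genomic_pos
                    inside = True
                    break
                prefix += e - s
        if not inside:
            return None
        return prefix if side == "up_to" else total - prefix


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE dialect: gene_id / transcript_id / gene_name attributes)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def load_annotation(gtf_path, mito_names: Iterable[str] = DEFAULT_MITO_NAMES
                    ) -> GenomeAnnotation:
    """Load a GENCODE-style GTF into an indexed :class:`GenomeAnnotation`.

    Only ``exon`` and ``CDS`` features are consulted. GTF 1-based inclusive
    coordinates are converted to 0-based half-open. A transcript with zero
    exon lines is skipped with a warning; an exon line missing gene_id or
    transcript_id raises :class:`AnnotationError` naming the line.
    """
    exon_rows: dict[str, list[Exon]] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tx -> (gene_id, gene_name)
    seen_tx: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, frame, attrs = fields[:9]
            if feature not in ("exon", "CDS", "transcript"):
                continue
            a = _parse_attrs(attrs)
            tx_id = a.get("transcript_id")
            gene_id = a.get("gene_id")
            if feature == "transcript":
                if tx_id and tx_id not in meta:
                    meta[tx_id] = (gene_id or "", a.get("gene_name", ""))
                    seen_tx.append(tx_id)
                continue
            if not tx_id or not gene_id:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: missing gene_id/transcript_id attribute")
            if tx_id not in meta:
                meta[tx_id] = (gene_id, a.get("gene_name", ""))
                seen_tx.append(tx_id)
            s, e = int(start) - 1, int(end)
            if feature == "exon":
                exon_rows.setdefault(tx_id, []).append(Exon(chrom, s, e, strand))
            else:
                cds_rows.setdefault(tx_id, []).append((s, e))
    transcripts: dict[str, TranscriptModel] = {}
    for tx_id in seen_tx:
        gene_id, gene_name = meta[tx_id]
        exons = exon_rows.get(tx_id, [])
        if not exons:
            warnings.warn(f"transcript {tx_id} has no exons; skipped")
            continue
        exons.sort(key=lambda e: e.start, reverse=(exons[0].strand == "-"))
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, gene_name=gene_name,
            exons=tuple(exons),
            cds_intervals=tuple(sorted(cds_rows.get(tx_id, ()))))
    return GenomeAnnotation(transcripts, mito_names=mito_names)


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write exon/CDS features back out (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx_id in sorted(ann.transcripts):
            tx = ann.transcripts[tx_id]
            attrs = (f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                     + (f' gene_name "{tx.gene_name}";' if tx.gene_name else ""))
            for e in sorted(tx.exons, key=lambda e: e.start):
                fh.write(f"{e.chrom}\tlongfuse\texon\t{e.start + 1}\t{e.end}\t.\t"
                         f"{e.strand}\t.\t{attrs}\n")
            for s, e in tx.cds_intervals:
                fh.write(f"{tx.chrom}\tlongfuse\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{tx.strand}\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# Transcriptome construction
# ---------------------------------------------------------------------------

def transcript_sequence(tx: TranscriptModel, genome) -> str:
    """Spliced transcript sequence; minus-strand models are reverse-complemented.

    ``genome`` is any mapping of chromosome name to an indexable sequence
    (dict of str, or a ``pyfaidx.Fasta``).
    """
    chrom_seq = genome[tx.chrom]
    parts = []
    for e in sorted(tx.exons, key=lambda e: e.start):
        piece = str(chrom_seq[e.start:e.end])
        if len(piece) != len(e):
            raise AnnotationError(
                f"exon {e.chrom}:{e.start}-{e.end} out of chromosome bounds")
        parts.append(piece)
    seq = "".join(parts)
    return reverse_complement(seq) if tx.strand == "-" else seq


def build_transcriptome(ann: GenomeAnnotation, genome,
                        out_fasta=None, line_width: int = 60) -> dict[str, str]:
    """Build all transcript sequences; optionally write a FASTA.

    Record ids are ``transcript_id|gene_key`` so downstream stages can recover
    the gene from the alignment target alone.
    """
    seqs = {tx_id: transcript_sequence(tx, genome)
            for tx_id, tx in ann.transcripts.items()}
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for tx_id in sorted(seqs):
                gene = ann.tx2gene[tx_id]
                fh.write(f">{tx_id}|{gene}\n")
                s = seqs[tx_id]
                for i in range(0, len(s), line_width):
                    fh.write(s[i:i + line_width] + "\n")
    return seqs
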