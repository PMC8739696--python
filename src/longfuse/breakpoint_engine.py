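"""From genome alignments of candidate reads to consolidated breakpoints.

Stages: raw junction extraction (strand- and orientation-aware), removal of
junctions explainable by regular transcription (intron-sized, transcription
order), exon-boundary anchoring within a 20 bp window, and support-weighted
clustering with a 50 bp Euclidean radius.

Breakpoint coordinates are 0-based inter-base cut points: the 5' position is
the cut after the last transcribed base of the upstream gene, the 3' position
the cut before the first base of the downstream gene. In this space annotated
exon ``start``/``end`` values are directly comparable to breakpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .alignment_io import AlignmentSegment, ReadAlignments
from .reference_model import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_INTRON_FILTER = 10_000
DEFAULT_ANCHOR_WINDOW = 20
DEFAULT_CONSISTENCY_TOL = 10
DEFAULT_CLUSTER_RADIUS = 50.0


@dataclass
class RawBreakpoint:
    read_id: str
    gene5: str
    chrom5: str
    pos5: int
    strand5: str
    gene3: str
    chrom3: str
    pos3: int
    strand3: str
    read_pos: int
    # signed read-space distance between the two alignment intervals at the
    # junction: positive = unaligned bases between them, negative = overlap
    q_gap: int = 0


@dataclass
class BreakpointCandidate:
    """A (possibly anchored) breakpoint with its supporting read set."""

    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    anchored: bool
    reads: set[str] = field(default_factory=set)
    # per-read read-coordinate junction positions, kept for multi-fusion linking
    read_pos: dict[str, int] = field(default_factory=dict)

    @property
    def group_key(self):
        return (self.gene5, self.gene3, self.chrom5, self.chrom3,
                self.strand5, self.strand3)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class Breakpoint:
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    boundary_anchored: bool
    supporting_reads: set[str]
    read_pos: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.supporting_reads)


def euclidean(a_pos5: int, a_pos3: int, b_pos5: int, b_pos3: int) -> float:
    return math.hypot(a_pos5 - b_pos5, a_pos3 - b_pos3)


# ---------------------------------------------------------------------------
# Raw breakpoint extraction
# ---------------------------------------------------------------------------

def _assign_gene(seg: AlignmentSegment, ann: GenomeAnnotation,
                 preferred: Optional[set[str]]) -> Optional[str]:
    """Gene for a genome segment: overlap of its spliced blocks with gene
    spans; the transcriptome-stage gene wins when it overlaps at all,
    otherwise the gene with the largest overlap (ties lexicographic)."""
    overlaps = ann.genes_overlapping(seg.target_id, seg.blocks())
    if not overlaps:
        return None
    if preferred:
        pref = [g for g in overlaps if g in preferred]
        if pref:
            return max(pref, key=lambda g: (overlaps[g], g))
    best = max(overlaps.values())
    return min(g for g, ov in overlaps.items() if ov == best)


def _cut_at_read_end(seg: AlignmentSegment) -> int:
    """Genomic cut point corresponding to the segment's end in read coords."""
    return seg.t_end if seg.strand == "+" else seg.t_start


def _cut_at_read_start(seg: AlignmentSegment) -> int:
    return seg.t_start if seg.strand == "+" else seg.t_end


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def extract_raw_breakpoints(reads: Iterable[ReadAlignments],
                            ann: GenomeAnnotation,
                            preferred_genes: Optional[Mapping[str, set[str]]] = None,
                            max_overlap: int = 15,
                            max_gap: int = 15,
                            ) -> list[RawBreakpoint]:
    """Adjacent two-gene segment pairs of each read become raw breakpoints.

    Reads whose genome segments all fall in one gene are dropped, as are
    segment pairs that do not abut in read coordinates (more than
    ``max_gap`` unaligned bases or ``max_overlap`` doubly-aligned bases at
    the junction): a junction is a single point in the read, and a hole in
    read coverage means the alignment ends do not locate it. Because cDNA
    reads come in both orientations, the mRNA sense is resolved by voting
    each segment's alignment strand against its gene's annotated strand;
    antisense reads have their pair order and strands mirrored so the
    reported 5'/3' roles follow transcription, not read order.
    """
    out: list[RawBreakpoint] = []
    for read in reads:
        segs = [s for s in read.segments if s.is_primary]
        assigned: list[tuple[str, AlignmentSegment]] = []
        pref = set(preferred_genes.get(read.read_id, ())) if preferred_genes else None
        for s in segs:
            gene = _assign_gene(s, ann, pref)
            if gene is not None:
                assigned.append((gene, s))
        if len({g for g, _ in assigned}) < 2:
            continue
        for (gene_a, a), (gene_b, b) in zip(assigned, assigned[1:]):
            if gene_a == gene_b:
                continue
            q_gap = b.q_start - a.q_end
            if q_gap > max_gap or -q_gap > max_overlap:
                continue
            vote = 0
            for g, s in ((gene_a, a), (gene_b, b)):
                vote += 1 if s.strand == ann.gene(g).strand else -1
            read_pos = (a.q_end + b.q_start) // 2
            if vote >= 0:  # read is the mRNA sense (ties default to sense)
                out.append(RawBreakpoint(
                    read_id=read.read_id,
                    gene5=gene_a, chrom5=a.target_id,
                    pos5=_cut_at_read_end(a), strand5=a.strand,
                    gene3=gene_b, chrom3=b.target_id,
                    pos3=_cut_at_read_start(b), strand3=b.strand,
                    read_pos=read_pos, q_gap=q_gap))
            else:  # antisense read: mirror the pair
                out.append(RawBreakpoint(
                    read_id=read.read_id,
                    gene5=gene_b, chrom5=b.target_id,
                    pos5=_cut_at_read_start(b), strand5=_flip(b.strand),
                    gene3=gene_a, chrom3=a.target_id,
                    pos3=_cut_at_read_end(a), strand3=_flip(a.strand),
                    read_pos=read_pos, q_gap=q_gap))
    return out


def filter_regular_transcription(raws: Iterable[RawBreakpoint],
                                 max_dist: int = DEFAULT_INTRON_FILTER
                                 ) -> list[RawBreakpoint]:
    """Drop junctions explainable by splicing within one transcription unit:
    same chromosome and strand, under ``max_dist`` apart, with the 3' side
    downstream of the 5' side in the strand's direction of transcription."""
    kept = []
    for r in raws:
        if (r.chrom5 == r.chrom3 and r.strand5 == r.strand3
                and abs(r.pos3 - r.pos5) < max_dist
                and ((r.strand5 == "+" and r.pos3 > r.pos5)
                     or (r.strand5 == "-" and r.pos3 < r.pos5))):
            continue
        kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Exon-boundary anchoring
# ---------------------------------------------------------------------------

def _donor_side(gene_strand: str) -> str:
    # transcription leaves a + gene at an exon end, a - gene at an exon start
    return "end" if gene_strand == "+" else "start"


def _acceptor_side(gene_strand: str) -> str:
    return "start" if gene_strand == "+" else "end"


def anchor_to_exons(raw: RawBreakpoint, ann: GenomeAnnotation,
                    window: int = DEFAULT_ANCHOR_WINDOW,
                    consistency_tol: int = DEFAULT_CONSISTENCY_TOL
                    ) -> BreakpointCandidate:
    """Snap a raw breakpoint to nearby exon boundaries of both genes.

    Candidate boundaries are the 5' gene's donor-side boundaries within
    ``window`` of pos5 and the 3' gene's acceptor-side boundaries within
    ``window`` of pos3. Each shift is expressed as a read-space displacement
    of the junction (so the two sides can be compared); a boundary pair is
    accepted only when the two shifted cuts land on the same read position
    within ``consistency_tol`` — the shifts must close the junction's
    read-space gap exactly, so the adjustment neither duplicates nor drops
    read sequence. Among valid pairs the smallest total shift wins.
    """
    g5 = ann.gene(raw.gene5)
    g3 = ann.gene(raw.gene3)
    b5s = [p for p, side in ann.boundaries_near(raw.gene5, raw.chrom5, raw.pos5, window)
           if side == _donor_side(g5.strand)]
    b3s = [p for p, side in ann.boundaries_near(raw.gene3, raw.chrom3, raw.pos3, window)
           if side == _acceptor_side(g3.strand)]
    best = None
    for b5 in b5s:
        d5 = b5 - raw.pos5 if raw.strand5 == "+" else raw.pos5 - b5
        for b3 in b3s:
            d3 = b3 - raw.pos3 if raw.strand3 == "+" else raw.pos3 - b3
            if abs(d5 - d3 - raw.q_gap) > consistency_tol:
                continue
            key = (abs(d5) + abs(d3), abs(d5), b5)
            if best is None or key < best[0]:
                best = (key, b5, b3)
    if best is None:
        pos5, pos3, anchored = raw.pos5, raw.pos3, False
    else:
        _, pos5, pos3 = best
        anchored = True
    return BreakpointCandidate(
        gene5=raw.gene5, gene3=raw.gene3,
        chrom5=raw.chrom5, pos5=pos5, strand5=raw.strand5,
        chrom3=raw.chrom3, pos3=pos3, strand3=raw.strand3,
        anchored=anchored, reads={raw.read_id},
        read_pos={raw.read_id: raw.read_pos})


def aggregate_candidates(cands: Iterable[BreakpointCandidate]
                         ) -> list[BreakpointCandidate]:
    """Merge candidates at identical positions/orientation into one record."""
    merged: dict[tuple, BreakpointCandidate] = {}
    for c in cands:
        key = (*c.group_key, c.pos5, c.pos3, c.anchored)
        if key in merged:
            merged[key].reads |= c.reads
            merged[key].read_pos.update(c.read_pos)
        else:
            merged[key] = replace(c, reads=set(c.reads),
                                  read_pos=dict(c.read_pos))
    return sorted(merged.values(),
                  key=lambda c: (c.group_key, c.pos5, c.pos3, not c.anchored))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_breakpoints(cands: list[BreakpointCandidate],
                        radius: float = DEFAULT_CLUSTER_RADIUS
                        ) -> list[Breakpoint]:
    """Consolidate nearby breakpoints within each gene-pair/orientation group.

    Non-anchored candidates are processed in ascending read-support order
    (ties: ascending pos5, then pos3); each donates its reads to the closest
    other surviving candidate within ``radius`` (Euclidean over the two
    genomic axes) and is deleted; with no neighbour in range it survives
    as its own breakpoint. Distances and support are recomputed after every
    merge. Survivors keep their own position, so a cluster containing an
    exon-boundary candidate is reported at the boundary.
    """
    groups: dict[tuple, list[BreakpointCandidate]] = {}
    for c in cands:
        groups.setdefault(c.group_key, []).append(
            replace(c, reads=set(c.reads), read_pos=dict(c.read_pos)))
    out: list[Breakpoint] = []
    for key in sorted(groups):
        members = groups[key]
        pending = [c for c in members if not c.anchored]
        while pending:
            pending.sort(key=lambda c: (c.n_reads, c.pos5, c.pos3))
            donor = pending[0]
            best = None
            for other in members:
                if other is donor:
                    continue
                d = euclidean(donor.pos5, donor.pos3, other.pos5, other.pos3)
                if d > radius:
                    continue
                k = (d, not other.anchored, other.pos5, other.pos3)
                if best is None or k < best[0]:
                    best = (k, other)
            pending.remove(donor)
            if best is not None:
                recipient = best[1]
                recipient.reads |= donor.reads
                recipient.read_pos.update(donor.read_pos)
                members.remove(donor)
        for c in sorted(members, key=lambda c: (c.pos5, c.pos3)):
            out.append(Breakpoint(
                gene5=c.gene5, gene3=c.gene3,
                chrom5=c.chrom5, pos5=c.pos5, strand5=c.strand5,
                chrom3=c.chrom3, pos3=c.pos3, strand3=c.strand3,
                boundary_anchored=c.anchored,
                supporting_reads=c.reads, read_pos=c.read_pos))
    return out


def write_breakpoint_tsv(bps: Iterable[Breakpoint], out_path) -> int:
    n = 0
    with open(out_path, "w") as fh:
        fh.write("gene5\tgene3\tchrom5\tpos5\tstrand5\tchrom3\tpos3\tstrand3\t"
                 "anchored\tn_reads\treads\n")
        for b in bps:
            fh.write(f"{b.gene5}\t{b.gene3}\t{b.chrom5}\t{b.pos5}\t{b.strand5}\t"
                     f"{b.chrom3}\t{b.pos3}\t{b.strand3}\t{int(b.boundary_anchored)}\t"
                     f"{b.n_reads}\t{','.join(sorted(b.supporting_reads))}\n")
            n += 1
    return n
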