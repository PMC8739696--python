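"""Select reads whose transcriptome alignments split across distinct genes.

A read is a fusion candidate when two of its alignment segments hit different
genes, abut in read coordinates (at most 15 bp of overlap and at most a 15 bp
gap) and map with the same read-vs-transcript strand — a genuine fusion mRNA
reads both partners in one direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from .alignment_io import AlignmentSegment, ReadAlignments

logger = logging.getLogger(__name__)

DEFAULT_MAX_OVERLAP = 15
DEFAULT_MAX_GAP = 15


@dataclass
class CandidateRead:
    read_id: str
    # ordered (gene, segment) hits along the read
    hits: list[tuple[str, AlignmentSegment]] = field(default_factory=list)
    # read-coordinate junction positions between consecutive hits
    junctions: list[int] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.hits]


def pair_qualifies(a: AlignmentSegment, b: AlignmentSegment,
                   gene_a: str, gene_b: str,
                   max_overlap: int = DEFAULT_MAX_OVERLAP,
                   max_gap: int = DEFAULT_MAX_GAP) -> bool:
    """Ordered pair rule: distinct genes, <=15 bp overlap/gap, same strand."""
    if gene_a == gene_b:
        return False
    if b.q_start < a.q_start:
        return False
    if a.strand != b.strand:
        return False
    overlap = max(0, a.q_end - b.q_start)
    gap = max(0, b.q_start - a.q_end)
    return overlap <= max_overlap and gap <= max_gap


def junction_position(a: AlignmentSegment, b: AlignmentSegment) -> int:
    """Read-coordinate junction: midpoint of the overlap or of the gap."""
    return (a.q_end + b.q_start) // 2


def reduce_chain(segments: list[AlignmentSegment], tx2gene: Mapping[str, str]
                 ) -> list[tuple[str, AlignmentSegment]]:
    """Reduce redundant isoform hits: among same-gene segments with
    overlapping query intervals keep the one with the largest n_match
    (ties: longer query span, then lexicographic target id)."""
    keyed = [(tx2gene[s.target_id], s) for s in segments]
    keyed.sort(key=lambda gs: (-gs[1].n_match, -gs[1].q_span, gs[1].target_id))
    kept: list[tuple[str, AlignmentSegment]] = []
    for gene, seg in keyed:
        shadowed = any(
            g == gene and seg.q_start < k.q_end and k.q_start < seg.q_end
            for g, k in kept)
        if not shadowed:
            kept.append((gene, seg))
    kept.sort(key=lambda gs: (gs[1].q_start, gs[1].q_end, gs[1].target_id))
    return kept


def find_candidates(reads: Iterable[ReadAlignments], tx2gene: Mapping[str, str],
                    max_overlap: int = DEFAULT_MAX_OVERLAP,
                    max_gap: int = DEFAULT_MAX_GAP,
                    min_seg_len: int = 0) -> Iterator[CandidateRead]:
    """Yield a :class:`CandidateRead` per read with a qualifying gene split.

    Secondary alignments and segments whose targets are unknown to
    ``tx2gene`` are ignored (the latter with a one-time warning). Reads with
    more than two gene hits are retained as multi-junction candidates when
    each adjacent pair independently qualifies.
    """
    warned_unknown = False
    for read in reads:
        segs = [s for s in read.segments if s.is_primary
                and s.q_span >= min_seg_len]
        known = [s for s in segs if s.target_id in tx2gene]
        if len(known) < len(segs) and not warned_unknown:
            logger.warning("dropping alignments to targets missing from the "
                           "transcript->gene map (first read: %s)", read.read_id)
            warned_unknown = True
        if len(known) < 2:
            continue
        chain = reduce_chain(known, tx2gene)
        # longest run of consecutive qualifying pairs
        best: list[int] = []
        run: list[int] = [0]
        for i in range(1, len(chain)):
            ga, a = chain[i - 1]
            gb, b = chain[i]
            if pair_qualifies(a, b, ga, gb, max_overlap, max_gap):
                run.append(i)
            else:
                if len(run) > len(best):
                    best = run
                run = [i]
        if len(run) > len(best):
            best = run
        if len(best) < 2:
            continue
        hits = [chain[i] for i in best]
        junctions = [junction_position(hits[i][1], hits[i + 1][1])
                     for i in range(len(hits) - 1)]
        yield CandidateRead(read_id=read.read_id, hits=hits, junctions=junctions)


def write_candidate_fasta(candidates: Iterable[CandidateRead],
                          read_seqs: Mapping[str, str], out_path) -> int:
    """Write each candidate read's full sequence once; error on missing ids."""
    seen: set[str] = set()
    missing: list[str] = []
    n = 0
    with open(out_path, "w") as fh:
        for c in candidates:
            if c.read_id in seen:
                continue
            seen.add(c.read_id)
            seq = read_seqs.get(c.read_id)
            if seq is None:
                missing.append(c.read_id)
                continue
            fh.write(f">{c.read_id}\n{seq}\n")
            n += 1
    if missing:
        raise KeyError(f"no sequence for candidate reads: {missing}")
    return n


def write_candidate_tsv(candidates: Iterable[CandidateRead], out_path) -> int:
    n = 0
    with open(out_path, "w") as fh:
        fh.write("read_id\tgenes\tjunction_read_pos\n")
        for c in candidates:
            fh.write(f"{c.read_id}\t{':'.join(c.genes)}\t"
                     f"{','.join(map(str, c.junctions))}\n")
            n += 1
    return n
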