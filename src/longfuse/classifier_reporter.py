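"""Classification, filtering, annotation, ranking and reporting of fusions.

Classes mirror the read-support/exon-boundary logic used for ranking noisy
long-read fusion evidence:

* ``HighConfidence`` — >=2 reads, breakpoint at annotated exon boundaries;
* ``LowConfidence`` — >=2 reads, breakpoint inside exon bodies (where
  library-preparation chimeras characteristically fall);
* ``PotentialTransSplicing`` — a single read at exon boundaries;
* single-read events away from boundaries are discarded.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .breakpoint_engine import Breakpoint, euclidean
from .reference_model import GenomeAnnotation

logger = logging.getLogger(__name__)

HIGH = "HighConfidence"
LOW = "LowConfidence"
TRANS = "PotentialTransSplicing"
CLASS_ORDER = {HIGH: 0, LOW: 1, TRANS: 2}

DEFAULT_READTHROUGH_DIST = 200_000

CSV_COLUMNS = ["sample", "fusion_genes", "chrom5", "base5", "strand5",
               "chrom3", "base3", "strand3", "spanning_reads",
               "classification", "inframe", "known", "read_ids"]


@dataclass
class FusionCall:
    breakpoint: Breakpoint
    classification: str
    in_frame: Optional[bool] = None  # None == unknown
    known: bool = False
    filtered_reason: str = "none"

    @property
    def gene5(self) -> str:
        return self.breakpoint.gene5

    @property
    def gene3(self) -> str:
        return self.breakpoint.gene3

    @property
    def n_reads(self) -> int:
        return self.breakpoint.n_reads


@dataclass
class MultiFusion:
    genes: tuple[str, ...]
    breakpoints: tuple[Breakpoint, ...]
    reads: set[str] = field(default_factory=set)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def classify(bp: Breakpoint) -> Optional[str]:
    """Class of a breakpoint, or None for discarded single-read non-boundary
    events."""
    if bp.n_reads >= 2:
        return HIGH if bp.boundary_anchored else LOW
    return TRANS if bp.boundary_anchored else None


def classify_all(bps: Iterable[Breakpoint]) -> tuple[list[FusionCall], list[Breakpoint]]:
    calls, discarded = [], []
    for bp in bps:
        cls = classify(bp)
        if cls is None:
            discarded.append(bp)
        else:
            calls.append(FusionCall(breakpoint=bp, classification=cls))
    return calls, discarded


def _is_read_through(bp: Breakpoint, max_dist: int) -> bool:
    if bp.chrom5 != bp.chrom3 or bp.strand5 != bp.strand3:
        return False
    if abs(bp.pos3 - bp.pos5) >= max_dist:
        return False
    return (bp.pos3 > bp.pos5) if bp.strand5 == "+" else (bp.pos3 < bp.pos5)


def filter_read_through(calls: Iterable[FusionCall],
                        max_dist: int = DEFAULT_READTHROUGH_DIST) -> list[FusionCall]:
    """Mark transcription running through into a same-strand downstream
    neighbour (breakpoints < ``max_dist`` apart in transcription order)."""
    out = list(calls)
    for c in out:
        if c.filtered_reason == "none" and _is_read_through(c.breakpoint, max_dist):
            c.filtered_reason = "read_through"
    return out


def filter_mitochondrial(calls: Iterable[FusionCall], ann: GenomeAnnotation,
                         enabled: bool = True) -> list[FusionCall]:
    out = list(calls)
    if not enabled:
        return out
    for c in out:
        if c.filtered_reason == "none" and (
                ann.is_mito(c.breakpoint.chrom5) or ann.is_mito(c.breakpoint.chrom3)):
            c.filtered_reason = "mitochondrial"
    return out


def annotate_frame(call: FusionCall, ann: GenomeAnnotation) -> Optional[bool]:
    """In-frame test: some (5' transcript, 3' transcript) pair has both cuts
    inside CDS with matching codon phase (coding prefix mod 3). Returns None
    (unknown) when no transcript pair places both sides in coding sequence.
    """
    bp = call.breakpoint
    phases5 = []
    for tx_id in ann.gene(bp.gene5).transcript_ids:
        p = ann.coding_prefix_length(tx_id, bp.pos5, "up_to")
        if p is not None:
            phases5.append(p % 3)
    phases3 = []
    for tx_id in ann.gene(bp.gene3).transcript_ids:
        p = ann.coding_prefix_length(tx_id, bp.pos3, "up_to")
        if p is not None:
            phases3.append(p % 3)
    if not phases5 or not phases3:
        call.in_frame = None
    else:
        call.in_frame = any(p5 == p3 for p5 in phases5 for p3 in phases3)
    return call.in_frame


def load_known_pairs(csv_path) -> set[frozenset]:
    """Two-column CSV of known fusion gene pairs (unordered)."""
    pairs: set[frozenset] = set()
    with open(csv_path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) < 2 or row[0].startswith("#"):
                continue
            pairs.add(frozenset((row[0].strip(), row[1].strip())))
    return pairs


def annotate_known(call: FusionCall, known_pairs: set[frozenset]) -> bool:
    call.known = frozenset((call.gene5, call.gene3)) in known_pairs
    return call.known


def sort_calls(calls: list[FusionCall]) -> list[FusionCall]:
    return sorted(calls, key=lambda c: (CLASS_ORDER[c.classification],
                                        -c.n_reads, c.gene5, c.breakpoint.pos5,
                                        c.gene3, c.breakpoint.pos3))


def calls_to_frame(calls: list[FusionCall], sample: str = "sample") -> pd.DataFrame:
    """Ranked table; genomic positions reported 1-based."""
    rows = []
    for c in sort_calls(calls):
        bp = c.breakpoint
        rows.append({
            "sample": sample,
            "fusion_genes": f"{bp.gene5}:{bp.gene3}",
            "chrom5": bp.chrom5, "base5": bp.pos5 + 1, "strand5": bp.strand5,
            "chrom3": bp.chrom3, "base3": bp.pos3 + 1, "strand3": bp.strand3,
            "spanning_reads": bp.n_reads,
            "classification": c.classification,
            "inframe": "unknown" if c.in_frame is None else str(c.in_frame).lower(),
            "known": str(c.known).lower(),
            "read_ids": ";".join(sorted(bp.supporting_reads)),
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def rank_and_report(calls: list[FusionCall], out_csv, sample: str = "sample",
                    keep_readthrough: bool = False) -> pd.DataFrame:
    """Write the main fusion table (filtered calls excluded unless kept)."""
    kept = [c for c in calls if c.filtered_reason == "none"
            or (keep_readthrough and c.filtered_reason == "read_through")]
    df = calls_to_frame(kept, sample=sample)
    df.to_csv(out_csv, index=False)
    return df


def report_filtered(calls: list[FusionCall], out_csv, sample: str = "sample"
                    ) -> pd.DataFrame:
    dropped = [c for c in calls if c.filtered_reason != "none"]
    df = calls_to_frame(dropped, sample=sample)
    df["filtered_reason"] = [c.filtered_reason for c in sort_calls(dropped)]
    df.to_csv(out_csv, index=False)
    return df


# ---------------------------------------------------------------------------
# Multi-gene (>=3 gene) fusion linking
# ---------------------------------------------------------------------------

def detect_multifusions(per_read_breakpoints: Mapping[str, list],
                        final_calls: list[FusionCall],
                        radius: float = 50.0) -> list[MultiFusion]:
    """Link reads carrying two or more junctions that each match a reported
    breakpoint (same gene pair/orientation, within ``radius`` Euclidean).

    ``per_read_breakpoints`` maps read id to its raw/anchored junction records
    (objects with gene5/gene3/chrom/strand/pos fields and ``read_pos``).
    Reads sharing the same ordered breakpoint tuple aggregate into one event.
    """
    kept = [c for c in final_calls if c.filtered_reason == "none"]
    by_group: dict[tuple, list[tuple[FusionCall, Breakpoint]]] = {}
    for c in kept:
        bp = c.breakpoint
        key = (bp.gene5, bp.gene3, bp.chrom5, bp.chrom3, bp.strand5, bp.strand3)
        by_group.setdefault(key, []).append((c, bp))
    events: dict[tuple, MultiFusion] = {}
    for read_id, junctions in per_read_breakpoints.items():
        matched: list[tuple[int, Breakpoint]] = []
        for j in junctions:
            key = (j.gene5, j.gene3, j.chrom5, j.chrom3, j.strand5, j.strand3)
            best = None
            for _, bp in by_group.get(key, ()):
                d = euclidean(j.pos5, j.pos3, bp.pos5, bp.pos3)
                if d <= radius and (best is None or d < best[0]):
                    best = (d, bp)
            if best is not None:
                matched.append((j.read_pos, best[1]))
        if len(matched) < 2:
            continue
        matched.sort(key=lambda t: t[0])
        bps = tuple(bp for _, bp in matched)
        genes = [bps[0].gene5]
        for bp in bps:
            genes.append(bp.gene3)
        key = tuple((bp.gene5, bp.gene3, bp.pos5, bp.pos3) for bp in bps)
        ev = events.get(key)
        if ev is None:
            events[key] = MultiFusion(genes=tuple(genes), breakpoints=bps,
                                      reads={read_id})
        else:
            ev.reads.add(read_id)
    return sorted(events.values(), key=lambda e: (-e.n_reads, e.genes))


def multifusions_to_frame(events: list[MultiFusion]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "genes": ":".join(e.genes),
            "breakpoints": ";".join(
                f"{bp.chrom5}:{bp.pos5 + 1}-{bp.chrom3}:{bp.pos3 + 1}"
                for bp in e.breakpoints),
            "n_reads": e.n_reads,
            "read_ids": ";".join(sorted(e.reads)),
        })
    return pd.DataFrame(rows, columns=["genes", "breakpoints", "n_reads", "read_ids"])
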