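"""Breakpoint extraction, intron-like filtering, anchoring, clustering."""

import math
import random

import pytest

from longfuse import breakpoint_engine as be
from longfuse.alignment_io import AlignmentSegment, ReadAlignments
from longfuse.reference_model import GenomeAnnotation
from conftest import make_transcript


@pytest.fixture
def span_ann():
    """Single-exon gene spans for extraction tests."""
    return GenomeAnnotation({
        "tA": make_transcript("tA", "geneA", "chr1", "+", [(1000, 5000)]),
        "tB": make_transcript("tB", "geneB", "chr2", "+", [(90000, 95000)]),
        "tC": make_transcript("tC", "geneC", "chr3", "-", [(6000, 8000)]),
    })


def gseg(chrom, t_start, t_end, q_start, q_end, strand="+", read_id="r"):
    return AlignmentSegment(read_id, 1000, q_start, q_end, strand, chrom,
                            t_start, t_end, n_match=q_end - q_start)


def read(*segs):
    return ReadAlignments(segs[0].read_id,
                          sorted(segs, key=lambda s: s.q_start))


class TestExtractRawBreakpoints:
    def test_plus_plus_pair_uses_end_and_start(self, span_ann):
        r = read(gseg("chr1", 4500, 5000, 0, 500),
                 gseg("chr2", 90000, 90500, 500, 1000))
        (bp,) = be.extract_raw_breakpoints([r], span_ann)
        assert (bp.gene5, bp.pos5, bp.gene3, bp.pos3) == ("geneA", 5000,
                                                          "geneB", 90000)

    def test_minus_strand_upstream_maps_end_to_t_start(self, span_ann):
        r = read(gseg("chr3", 7000, 7500, 0, 500, strand="-"),
                 gseg("chr2", 90000, 90500, 500, 1000))
        (bp,) = be.extract_raw_breakpoints([r], span_ann)
        assert (bp.gene5, bp.pos5, bp.strand5) == ("geneC", 7000, "-")

    def test_single_gene_read_dropped(self, span_ann):
        r = read(gseg("chr1", 1000, 2000, 0, 500),
                 gseg("chr1", 3000, 4000, 500, 1000))
        assert be.extract_raw_breakpoints([r], span_ann) == []

    def test_junction_hole_over_15bp_dropped(self, span_ann):
        r = read(gseg("chr1", 4500, 5000, 0, 500),
                 gseg("chr2", 90000, 90500, 516, 1000))
        assert be.extract_raw_breakpoints([r], span_ann) == []
        r2 = read(gseg("chr1", 4500, 5000, 0, 500),
                  gseg("chr2", 90000, 90500, 480, 1000))  # 20 bp overlap
        assert be.extract_raw_breakpoints([r2], span_ann) == []

    def test_antisense_read_is_mirrored(self, span_ann):
        # reverse-complement read of a geneA->geneB fusion: geneB part first
        r = read(gseg("chr2", 90000, 90500, 0, 500, strand="-"),
                 gseg("chr1", 4500, 5000, 500, 1000, strand="-"))
        (bp,) = be.extract_raw_breakpoints([r], span_ann)
        assert (bp.gene5, bp.pos5, bp.strand5) == ("geneA", 5000, "+")
        assert (bp.gene3, bp.pos3, bp.strand3) == ("geneB", 90000, "+")

    def test_preferred_gene_wins_overlap_ties(self, span_ann):
        r = read(gseg("chr1", 4500, 5000, 0, 500),
                 gseg("chr2", 90000, 90500, 500, 1000))
        bps = be.extract_raw_breakpoints([r], span_ann,
                                         preferred_genes={"r": {"geneA", "geneB"}})
        assert len(bps) == 1


def raw(pos5, pos3, strand5="+", strand3="+", chrom5="chr1", chrom3="chr1",
        q_gap=0, read_id="r"):
    return be.RawBreakpoint(read_id=read_id, gene5="geneA", chrom5=chrom5,
                            pos5=pos5, strand5=strand5, gene3="geneB",
                            chrom3=chrom3, pos3=pos3, strand3=strand3,
                            read_pos=500, q_gap=q_gap)


class TestRegularTranscriptionFilter:
    def test_intron_sized_in_transcription_order_removed(self):
        assert be.filter_regular_transcription([raw(1000, 9000)]) == []

    def test_beyond_threshold_kept(self):
        assert len(be.filter_regular_transcription([raw(1000, 12000)])) == 1

    def test_wrong_order_kept(self):
        assert len(be.filter_regular_transcription([raw(9000, 1000)])) == 1

    def test_minus_strand_order_mirrored(self):
        assert be.filter_regular_transcription(
            [raw(9000, 1000, strand5="-", strand3="-")]) == []
        assert len(be.filter_regular_transcription(
            [raw(1000, 9000, strand5="-", strand3="-")])) == 1

    def test_different_chromosomes_kept(self):
        assert len(be.filter_regular_transcription(
            [raw(1000, 9000, chrom3="chr2")])) == 1


@pytest.fixture
def anchor_ann():
    return GenomeAnnotation({
        "tA": make_transcript("tA", "geneA", "chr1", "+",
                              [(1000, 2000), (3000, 4000)]),
        "tB": make_transcript("tB", "geneB", "chr2", "+",
                              [(90012, 90500), (91000, 91500)]),
    })


class TestAnchorToExons:
    def anchor(self, r, ann, **kw):
        return be.anchor_to_exons(r, ann, **kw)

    def test_consistent_shifts_anchor_both_sides(self, anchor_ann):
        c = self.anchor(raw(1988, 90000, chrom3="chr2"), anchor_ann)
        assert c.anchored and (c.pos5, c.pos3) == (2000, 90012)

    def test_boundary_beyond_window_unanchored(self, anchor_ann):
        c = self.anchor(raw(1975, 90012, chrom3="chr2"), anchor_ann)
        assert not c.anchored and (c.pos5, c.pos3) == (1975, 90012)

    def test_inconsistent_shifts_rejected(self, anchor_ann):
        # d5=+10 but only d3=-10 available: |d5-d3| = 20 > tol
        c = self.anchor(raw(1990, 90022, chrom3="chr2"), anchor_ann,
                        consistency_tol=10)
        assert not c.anchored

    def test_read_gap_enters_consistency(self, anchor_ann):
        # alignment hole of 12 bases: shifts must close it, not cancel out
        c = self.anchor(raw(1988, 90012, chrom3="chr2", q_gap=12), anchor_ann)
        assert c.anchored and (c.pos5, c.pos3) == (2000, 90012)
        c2 = self.anchor(raw(1988, 90012, chrom3="chr2", q_gap=0), anchor_ann)
        assert not c2.anchored  # d5=+12, d3=0 do not agree

    def test_anchoring_is_idempotent(self, anchor_ann):
        c = self.anchor(raw(2000, 90012, chrom3="chr2"), anchor_ann)
        assert c.anchored and (c.pos5, c.pos3) == (2000, 90012)

    def test_anchored_output_positions_are_annotated_boundaries(self, anchor_ann):
        rng = random.Random(5)
        for _ in range(200):
            r = raw(2000 + rng.randint(-30, 30), 90012 + rng.randint(-30, 30),
                    chrom3="chr2", q_gap=rng.randint(-15, 15))
            c = self.anchor(r, anchor_ann)
            if c.anchored:
                assert c.pos5 in anchor_ann.boundary_set("geneA", "end")
                assert c.pos3 in anchor_ann.boundary_set("geneB", "start")


def cand(pos5, pos3, reads, anchored=False):
    return be.BreakpointCandidate(
        gene5="geneA", gene3="geneB", chrom5="chr1", pos5=pos5, strand5="+",
        chrom3="chr2", pos3=pos3, strand3="+", anchored=anchored,
        reads=set(reads), read_pos={r: 0 for r in reads})


class TestClusterBreakpoints:
    def test_low_support_donates_to_nearest_within_radius(self):
        out = be.cluster_breakpoints([cand(1000, 5000, ["r1"]),
                                      cand(1030, 5030, ["r2", "r3", "r4"])])
        assert len(out) == 1
        (bp,) = out
        assert (bp.pos5, bp.pos3) == (1030, 5030)
        assert bp.supporting_reads == {"r1", "r2", "r3", "r4"}

    def test_beyond_radius_stays_separate(self):
        out = be.cluster_breakpoints([cand(1000, 5000, ["r1"]),
                                      cand(1040, 5040, ["r2", "r3"])])
        assert len(out) == 2  # sqrt(40^2+40^2) ~ 56.6 > 50

    def test_lone_unanchored_candidate_reported(self):
        (bp,) = be.cluster_breakpoints([cand(1000, 5000, ["r1"])])
        assert (bp.pos5, bp.pos3, bp.boundary_anchored) == (1000, 5000, False)

    def test_cluster_with_anchored_member_reports_boundary(self):
        out = be.cluster_breakpoints([cand(1000, 5000, ["r1", "r2"], anchored=True),
                                      cand(1030, 5030, ["r3"])])
        (bp,) = out
        assert bp.boundary_anchored and (bp.pos5, bp.pos3) == (1000, 5000)
        assert bp.n_reads == 3

    def test_radius_zero_preserves_positions(self):
        cands = [cand(1000, 5000, ["r1"]), cand(1001, 5001, ["r2"])]
        out = be.cluster_breakpoints(cands, radius=0)
        assert sorted((b.pos5, b.pos3) for b in out) == [(1000, 5000), (1001, 5001)]

    def test_read_conservation(self):
        rng = random.Random(21)
        for _ in range(100):
            cands, all_reads = _random_instance(rng)
            out = be.cluster_breakpoints(cands)
            got = set()
            for b in out:
                assert not (got & b.supporting_reads)
                got |= b.supporting_reads
            assert got == all_reads

    def test_matches_brute_force_iteration(self):
        rng = random.Random(4242)
        for _ in range(500):
            cands, _ = _random_instance(rng)
            ours = {(b.pos5, b.pos3, b.boundary_anchored,
                     frozenset(b.supporting_reads))
                    for b in be.cluster_breakpoints(cands, radius=50)}
            assert ours == _oracle_cluster(cands, radius=50)


def _random_instance(rng):
    n = rng.randint(1, 8)
    positions = set()
    while len(positions) < n:
        positions.add((rng.randrange(0, 130, 7), rng.randrange(0, 130, 7)))
    cands = []
    next_read = 0
    all_reads = set()
    for pos5, pos3 in sorted(positions):
        k = rng.randint(1, 3)
        reads = {f"r{next_read + i}" for i in range(k)}
        next_read += k
        all_reads |= reads
        cands.append(cand(pos5, pos3, reads, anchored=rng.random() < 0.3))
    return cands, all_reads


def _oracle_cluster(cands, radius):
    """Independent naive re-implementation of the clustering iteration."""
    state = [{"pos5": c.pos5, "pos3": c.pos3, "anchored": c.anchored,
              "reads": set(c.reads)} for c in cands]
    unprocessed = [s for s in state if not s["anchored"]]
    while unprocessed:
        donor = min(unprocessed,
                    key=lambda s: (len(s["reads"]), s["pos5"], s["pos3"]))
        unprocessed.remove(donor)
        neighbours = []
        for other in state:
            if other is donor:
                continue
            d = math.hypot(donor["pos5"] - other["pos5"],
                           donor["pos3"] - other["pos3"])
            if d <= radius:
                neighbours.append(
                    ((d, not other["anchored"], other["pos5"], other["pos3"]),
                     other))
        if neighbours:
            neighbours.sort(key=lambda t: t[0])
            target = neighbours[0][1]
            target["reads"] |= donor["reads"]
            state.remove(donor)
    return {(s["pos5"], s["pos3"], s["anchored"], frozenset(s["reads"]))
            for s in state}
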