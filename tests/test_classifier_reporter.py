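"""Classification, filters, frame/known annotation, ranking, multi-fusions."""

import itertools

import pytest

from longfuse import classifier_reporter as cr
from longfuse.breakpoint_engine import Breakpoint, RawBreakpoint
from longfuse.reference_model import GenomeAnnotation
from conftest import make_transcript


def bp(n_reads=2, anchored=True, gene5="geneA", gene3="geneB", chrom5="chr1",
       pos5=10_000, strand5="+", chrom3="chr2", pos3=20_000, strand3="+"):
    reads = {f"r{i}" for i in range(n_reads)}
    return Breakpoint(gene5=gene5, gene3=gene3, chrom5=chrom5, pos5=pos5,
                      strand5=strand5, chrom3=chrom3, pos3=pos3,
                      strand3=strand3, boundary_anchored=anchored,
                      supporting_reads=reads,
                      read_pos={r: 100 for r in reads})


class TestClassify:
    @pytest.mark.parametrize("n_reads,anchored,expected", [
        (2, True, cr.HIGH),
        (5, True, cr.HIGH),
        (2, False, cr.LOW),
        (1, True, cr.TRANS),
        (1, False, None),
    ])
    def test_mapping(self, n_reads, anchored, expected):
        assert cr.classify(bp(n_reads=n_reads, anchored=anchored)) == expected

    def test_partition_is_total_and_exclusive(self):
        for n_reads, anchored in itertools.product([1, 2, 3, 10], [True, False]):
            calls, discarded = cr.classify_all([bp(n_reads=n_reads,
                                                   anchored=anchored)])
            assert len(calls) + len(discarded) == 1


class TestFilters:
    def test_read_through_within_200kb_in_order_filtered(self):
        calls, _ = cr.classify_all([bp(chrom3="chr1", pos5=10_000, pos3=160_000)])
        assert cr.filter_read_through(calls)[0].filtered_reason == "read_through"

    def test_beyond_200kb_kept(self):
        calls, _ = cr.classify_all([bp(chrom3="chr1", pos5=10_000, pos3=274_000)])
        assert cr.filter_read_through(calls)[0].filtered_reason == "none"

    def test_opposite_strand_kept(self):
        calls, _ = cr.classify_all([bp(chrom3="chr1", pos5=10_000, pos3=60_000,
                                       strand3="-")])
        assert cr.filter_read_through(calls)[0].filtered_reason == "none"

    def test_minus_strand_order_mirrored(self):
        calls, _ = cr.classify_all([bp(chrom3="chr1", pos5=160_000, pos3=10_000,
                                       strand5="-", strand3="-")])
        assert cr.filter_read_through(calls)[0].filtered_reason == "read_through"

    @pytest.fixture
    def mito_ann(self):
        return GenomeAnnotation({
            "tM": make_transcript("tM", "geneM", "chrM", "+", [(0, 1000)]),
            "tA": make_transcript("tA", "geneA", "chr1", "+", [(0, 1000)]),
        })

    def test_mitochondrial_filtered_when_enabled(self, mito_ann):
        calls, _ = cr.classify_all([bp(chrom5="chrM")])
        assert cr.filter_mitochondrial(calls, mito_ann)[0].filtered_reason == \
            "mitochondrial"

    def test_mitochondrial_kept_when_disabled(self, mito_ann):
        calls, _ = cr.classify_all([bp(chrom5="chrM")])
        assert cr.filter_mitochondrial(calls, mito_ann, enabled=False)[0]\
            .filtered_reason == "none"

    def test_non_mito_kept(self, mito_ann):
        calls, _ = cr.classify_all([bp()])
        assert cr.filter_mitochondrial(calls, mito_ann)[0].filtered_reason == "none"

    def test_filters_commute(self, mito_ann):
        def fresh():
            calls, _ = cr.classify_all([
                bp(chrom5="chrM"),
                bp(chrom3="chr1", pos5=10_000, pos3=60_000),
                bp(pos3=999_000)])
            return calls

        ab = cr.filter_mitochondrial(cr.filter_read_through(fresh()), mito_ann)
        ba = cr.filter_read_through(cr.filter_mitochondrial(fresh(), mito_ann))
        assert [c.filtered_reason for c in ab] == [c.filtered_reason for c in ba]


class TestAnnotateFrame:
    @pytest.fixture
    def cds_ann(self):
        # geneA: exon [0,1000), CDS [100,700); geneB: exon [2000,3000), CDS [2000,2600)
        return GenomeAnnotation({
            "tA": make_transcript("tA", "geneA", "chr1", "+", [(0, 1000)],
                                  cds=[(100, 700)]),
            "tB": make_transcript("tB", "geneB", "chr2", "+", [(1800, 3000)],
                                  cds=[(2000, 2600)]),
        })

    def test_matching_phase_in_frame(self, cds_ann):
        call = cr.FusionCall(bp(pos5=400, pos3=2000), cr.HIGH)  # prefix 300, offset 0
        assert cr.annotate_frame(call, cds_ann) is True

    def test_phase_shift_out_of_frame(self, cds_ann):
        call = cr.FusionCall(bp(pos5=401, pos3=2000), cr.HIGH)  # prefix 301
        assert cr.annotate_frame(call, cds_ann) is False

    def test_utr_breakpoint_unknown(self, cds_ann):
        call = cr.FusionCall(bp(pos5=50, pos3=2000), cr.HIGH)  # 5'UTR
        assert cr.annotate_frame(call, cds_ann) is None


class TestAnnotateKnown:
    def test_unordered_match(self, tmp_path):
        p = tmp_path / "known.csv"
        p.write_text("ABL1,BCR\nEML4,ALK\n")
        pairs = cr.load_known_pairs(p)
        call = cr.FusionCall(bp(gene5="BCR", gene3="ABL1"), cr.HIGH)
        assert cr.annotate_known(call, pairs) is True

    def test_absent_pair_false(self, tmp_path):
        p = tmp_path / "known.csv"
        p.write_text("ABL1,BCR\n")
        call = cr.FusionCall(bp(gene5="geneA", gene3="geneB"), cr.HIGH)
        assert cr.annotate_known(call, cr.load_known_pairs(p)) is False

    def test_empty_list_all_false(self, tmp_path):
        p = tmp_path / "known.csv"
        p.write_text("")
        call = cr.FusionCall(bp(), cr.HIGH)
        assert cr.annotate_known(call, cr.load_known_pairs(p)) is False


class TestRankAndReport:
    def make_calls(self):
        calls, _ = cr.classify_all([
            bp(n_reads=2, anchored=True, gene5="geneC"),
            bp(n_reads=3, anchored=True, gene5="geneA"),
            bp(n_reads=9, anchored=False, gene5="geneB"),
            bp(n_reads=1, anchored=True, gene5="geneD"),
        ])
        return calls

    def test_class_then_support_ordering(self, tmp_path):
        df = cr.rank_and_report(self.make_calls(), tmp_path / "out.csv")
        assert list(df.classification) == [cr.HIGH, cr.HIGH, cr.LOW, cr.TRANS]
        assert list(df.spanning_reads)[:2] == [3, 2]

    def test_positions_reported_one_based(self, tmp_path):
        calls, _ = cr.classify_all([bp(pos5=4999, pos3=19_999)])
        df = cr.rank_and_report(calls, tmp_path / "out.csv")
        assert df.base5.iloc[0] == 5000 and df.base3.iloc[0] == 20_000

    def test_schema_stable(self, tmp_path):
        df = cr.rank_and_report(self.make_calls(), tmp_path / "out.csv")
        assert list(df.columns) == cr.CSV_COLUMNS

    def test_filtered_calls_excluded_unless_kept(self, tmp_path):
        calls, _ = cr.classify_all([bp(chrom3="chr1", pos5=10_000, pos3=60_000),
                                    bp()])
        calls = cr.filter_read_through(calls)
        assert len(cr.rank_and_report(calls, tmp_path / "a.csv")) == 1
        assert len(cr.rank_and_report(calls, tmp_path / "b.csv",
                                      keep_readthrough=True)) == 2


class TestMultiFusions:
    def setup_calls(self):
        bp_ab = bp(gene5="geneA", gene3="geneB", pos5=1000, pos3=5000, n_reads=6)
        bp_bc = bp(gene5="geneB", gene3="geneC", chrom5="chr2", pos5=6000,
                   chrom3="chr3", pos3=9000, n_reads=6)
        calls, _ = cr.classify_all([bp_ab, bp_bc])
        return calls

    def junction(self, gene5, gene3, chrom5, pos5, chrom3, pos3, read_pos):
        return RawBreakpoint(read_id="x", gene5=gene5, chrom5=chrom5, pos5=pos5,
                             strand5="+", gene3=gene3, chrom3=chrom3, pos3=pos3,
                             strand3="+", read_pos=read_pos)

    def per_read(self, read_ids):
        return {rid: [
            self.junction("geneA", "geneB", "chr1", 1010, "chr2", 5010, 300),
            self.junction("geneB", "geneC", "chr2", 6010, "chr3", 9010, 800),
        ] for rid in read_ids}

    def test_two_matching_junctions_link_three_genes(self):
        (ev,) = cr.detect_multifusions(self.per_read(["r0"]), self.setup_calls())
        assert ev.genes == ("geneA", "geneB", "geneC")
        assert ev.n_reads == 1

    def test_reads_sharing_breakpoints_aggregate(self):
        (ev,) = cr.detect_multifusions(
            self.per_read([f"r{i}" for i in range(6)]), self.setup_calls())
        assert ev.n_reads == 6

    def test_single_junction_read_ignored(self):
        per_read = {"r0": [self.junction("geneA", "geneB", "chr1", 1010,
                                         "chr2", 5010, 300)]}
        assert cr.detect_multifusions(per_read, self.setup_calls()) == []

    def test_gene_chain_follows_read_order(self):
        per_read = {"r0": [
            self.junction("geneB", "geneC", "chr2", 6010, "chr3", 9010, 800),
            self.junction("geneA", "geneB", "chr1", 1010, "chr2", 5010, 300),
        ]}
        (ev,) = cr.detect_multifusions(per_read, self.setup_calls())
        assert ev.genes == ("geneA", "geneB", "geneC")
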