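"""Chimeric gene models, expression filter, intersection-nonempty counting."""

import numpy as np
import pandas as pd
import pytest

from subsetnet import genemodel, simulate
from subsetnet.config import FormatError

COLS = genemodel.EXON_COLUMNS


def exon_table(rows):
    return pd.DataFrame(rows, columns=COLS)


def brute_force_count(exons: pd.DataFrame, alignments: pd.DataFrame) -> dict:
    """Independent base-level oracle for intersection-nonempty counting."""
    coding = exons[exons["biotype"] == "protein_coding"]
    counts: dict = {}
    for rec in alignments.itertuples(index=False):
        if rec.multiplicity > 1:
            continue
        sets = []
        for base in range(rec.start, rec.end):
            here = set()
            for ex in coding.itertuples(index=False):
                if ex.chrom == rec.chrom and ex.start <= base < ex.end:
                    here.add(ex.gene_id)
            if here:
                sets.append(here)
        if not sets:
            continue
        assigned = set.intersection(*sets)
        if len(assigned) == 1:
            g = assigned.pop()
            counts[g] = counts.get(g, 0) + 1
    return counts


class TestBuildChimericModel:
    def test_overlapping_transcripts_merge(self):
        rows = [
            ("g1", "t1", "chr1", 100, 200, "+", "protein_coding"),
            ("g1", "t1", "chr1", 300, 400, "+", "protein_coding"),
            ("g1", "t2", "chr1", 150, 250, "+", "protein_coding"),
        ]
        model = genemodel.build_chimeric_model(exon_table(rows))
        assert model.exons["g1"] == [(100, 250), (300, 400)]
        assert model.exonic_length("g1") == 250
        assert model.exon_count("g1") == 2

    def test_single_transcript_is_identity(self):
        rows = [("g1", "t1", "chr1", 10, 50, "-", "protein_coding"),
                ("g1", "t1", "chr1", 80, 120, "-", "protein_coding")]
        model = genemodel.build_chimeric_model(exon_table(rows))
        assert model.exons["g1"] == [(10, 50), (80, 120)]

    def test_tiling_transcripts_collapse_to_one_exon(self):
        # three transcripts tiling [0,300) in overlapping 150-bp exons
        rows = [("g1", f"t{i}", "chr1", s, s + 150, "+", "protein_coding")
                for i, s in enumerate((0, 75, 150))]
        model = genemodel.build_chimeric_model(exon_table(rows))
        # brute-force basepair-marking oracle for the union
        covered = np.zeros(400, dtype=bool)
        for _, _, _, s, e, _, _ in rows:
            covered[s:e] = True
        breaks = np.flatnonzero(np.diff(covered.astype(int)))
        assert model.exons["g1"] == [(0, 300)]
        assert list(breaks + 1) == [300]

    def test_non_coding_transcripts_dropped(self):
        rows = [("g1", "t1", "chr1", 0, 100, "+", "protein_coding"),
                ("g1", "nc", "chr1", 500, 900, "+", "lincRNA"),
                ("g2", "nc2", "chr1", 1000, 1100, "+", "lincRNA")]
        model = genemodel.build_chimeric_model(exon_table(rows))
        assert model.exons["g1"] == [(0, 100)]
        assert "g2" not in model.exons  # zero coding transcripts -> absent

    def test_idempotent_on_own_output(self, toy_model):
        again = genemodel.build_chimeric_model(toy_model.to_exon_table())
        assert again.exons == toy_model.exons

    def test_bad_record_named_in_error(self):
        rows = [("gX", "tX", "chr1", 500, 400, "+", "protein_coding")]
        with pytest.raises(FormatError, match="gX"):
            genemodel.build_chimeric_model(exon_table(rows))

    def test_gtf_reader_converts_coordinates(self, tmp_path):
        """GTF is 1-based closed; the reader emits 0-based half-open."""
        gtf = tmp_path / "toy.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1"; gene_biotype "protein_coding";'
        gtf.write_text(
            "\t".join(["chr1", "src", "exon", "101", "200", ".", "+", ".",
                       attrs]) + "\n" +
            "\t".join(["chr1", "src", "exon", "301", "400", ".", "+", ".",
                       attrs]) + "\n")
        table = genemodel.read_gtf(gtf)
        model = genemodel.build_chimeric_model(table)
        assert model.exons["g1"] == [(100, 200), (300, 400)]
        assert model.exonic_length("g1") == 200


def _aln(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "read_id", "multiplicity"])


class TestExonCoverageFilter:
    @pytest.fixture()
    def model(self):
        rows = [
            # two-exon gene
            ("g2x", "t", "chr1", 0, 100, "+", "protein_coding"),
            ("g2x", "t", "chr1", 200, 300, "+", "protein_coding"),
            # four-exon gene
            *[("g4x", "t", "chr1", s, s + 50, "+", "protein_coding")
              for s in (1000, 1200, 1400, 1600)],
        ]
        return genemodel.build_chimeric_model(exon_table(rows))

    def test_exactly_half_coverage_is_kept(self, model):
        # one of two exons hit in every sample: fraction 0.5, not < 0.5
        aln = _aln([("chr1", 10, 90, "+", "r1", 1)])
        kept, dropped = genemodel.exon_coverage_filter(
            model, {"s1": aln, "s2": aln})
        assert "g2x" in kept

    def test_quarter_coverage_everywhere_drops(self, model):
        aln = _aln([("chr1", 1010, 1040, "+", "r1", 1)])
        kept, dropped = genemodel.exon_coverage_filter(
            model, {"s1": aln, "s2": aln})
        assert "g4x" in dropped

    def test_one_expressed_sample_rescues(self, model):
        low = _aln([("chr1", 1010, 1040, "+", "r1", 1)])
        full = _aln([("chr1", s + 5, s + 45, "+", f"r{s}", 1)
                     for s in (1000, 1200, 1400, 1600)])
        kept, _ = genemodel.exon_coverage_filter(
            model, {"s1": low, "s2": low, "s3": low, "s4": full})
        assert "g4x" in kept

    def test_empty_model_rejected(self):
        empty = genemodel.ChimericGeneModel(exons={}, chroms={}, strands={})
        with pytest.raises(ValueError):
            genemodel.exon_coverage_filter(empty, {"s": _aln([])})


class TestCountReads:
    @pytest.fixture()
    def two_gene_model(self):
        rows = [
            ("gA", "t", "chr1", 0, 100, "+", "protein_coding"),
            ("gA", "t", "chr1", 200, 300, "+", "protein_coding"),
            ("gB", "t", "chr1", 280, 400, "+", "protein_coding"),
        ]
        return genemodel.build_chimeric_model(exon_table(rows))

    def test_unique_reads_inside_one_gene(self, two_gene_model):
        aln = _aln([("chr1", 5 * i, 5 * i + 40, "+", f"r{i}", 1)
                    for i in range(10)])
        counts = genemodel.count_reads(two_gene_model, aln)
        assert counts["gA"] == 10 and counts["gB"] == 0

    def test_read_spanning_two_genes_discarded(self, two_gene_model):
        aln = _aln([("chr1", 270, 350, "+", "amb", 1)])
        counts = genemodel.count_reads(two_gene_model, aln)
        assert counts.sum() == 0

    def test_read_in_shared_region_only_is_ambiguous(self, two_gene_model):
        aln = _aln([("chr1", 285, 295, "+", "shared", 1)])
        assert genemodel.count_reads(two_gene_model, aln).sum() == 0

    def test_multimapped_discarded(self, two_gene_model):
        aln = _aln([("chr1", 10, 50, "+", "mm", 3)])
        assert genemodel.count_reads(two_gene_model, aln).sum() == 0

    def test_unknown_chromosome_skipped(self, two_gene_model, caplog):
        aln = _aln([("chrUn", 10, 50, "+", "r", 1),
                    ("chr1", 10, 50, "+", "ok", 1)])
        counts = genemodel.count_reads(two_gene_model, aln)
        assert counts["gA"] == 1

    def test_strand_flip_invariance(self, toy_model, toy_alignments):
        records, _ = toy_alignments
        flipped = records.assign(
            strand=records["strand"].map({"+": "-", "-": "+"}))
        c1 = genemodel.count_reads(toy_model, records)
        c2 = genemodel.count_reads(toy_model, flipped)
        pd.testing.assert_series_equal(c1, c2)

    def test_matches_truth_labels_and_brute_force(self, toy_model, toy_alignments):
        """Counts equal both the generator's countable labels and an
        independent base-level scan of the exon table."""
        records, labels = toy_alignments
        counts = genemodel.count_reads(toy_model, records)
        expected = labels[labels.str.startswith("countable:")] \
            .str.split(":").str[1].value_counts()
        for gene in counts.index:
            assert counts[gene] == expected.get(gene, 0)
        oracle = brute_force_count(toy_model.to_exon_table(), records)
        for gene in counts.index:
            assert counts[gene] == oracle.get(gene, 0)

    def test_conservation_bound(self, toy_model, toy_alignments):
        records, _ = toy_alignments
        counts = genemodel.count_reads(toy_model, records)
        assert counts.sum() <= (records["multiplicity"] == 1).sum()
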