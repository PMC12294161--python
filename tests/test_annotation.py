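"""Promoter/exon/intron/boundary/intergenic classification of fragments."""

import numpy as np
import pandas as pd
import pytest

from dmfkit.annotation import (
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    AnnotationLabel,
    GeneIndex,
    GeneModel,
    annotate_catalog,
    classify_fragment,
    load_gene_models,
)
from dmfkit.digest import FragmentCatalog

PLUS = GeneModel("gA", "chr1", "+", 20000, 32000, ((20000, 20300), (20700, 21000), (28000, 32000)))
MINUS = GeneModel("gB", "chr1", "-", 60000, 72000, ((60000, 64000), (66000, 72000)))


def catalog_from_intervals(intervals):
    frame = pd.DataFrame(
        [
            ("chr1", s, e, f"chr1:{s}-{e}", e - s, False, 0)
            for s, e in intervals
        ],
        columns=["chrom", "start", "end", "fragment_id", "length", "terminal", "n_cpg"],
    )
    return FragmentCatalog(frame=frame)


def brute_force_classify(chrom, start, end, models):
    """O(n*m) reference: same precedence rules, no interval index."""
    rank = {"promoter": 0, "exon_intron_boundary": 1, "exon": 2, "intron": 3}

    def overlaps(a, b, c, d):
        return a < d and c < b

    best = None
    for m in models:
        if m.chrom != chrom:
            continue
        ps, pe = m.promoter_window()
        label = None
        if overlaps(start, end, ps, pe):
            label = "promoter"
        elif overlaps(start, end, m.start, m.end):
            in_ex = any(overlaps(start, end, s, e) for s, e in m.exons)
            in_in = any(overlaps(start, end, s, e) for s, e in m.introns())
            label = (
                "exon_intron_boundary" if in_ex and in_in else "exon" if in_ex else "intron"
            )
        if label is None:
            continue
        key = (rank[label], abs(m.tss_distance(start, end)), m.gene_id, label, m)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return AnnotationLabel("intergenic", None, None)
    return AnnotationLabel(best[3], best[4].gene_id, best[4].tss_distance(start, end))


class TestGeneModel:
    def test_minus_strand_tss(self):
        g = GeneModel("g", "c", "-", 100, 500, ((100, 500),))
        assert g.tss == 499

    def test_promoter_window_strand_aware(self):
        assert PLUS.promoter_window() == (
            20000 - PROMOTER_UPSTREAM,
            20000 + PROMOTER_DOWNSTREAM + 1,
        )
        lo, hi = MINUS.promoter_window()
        assert lo == MINUS.tss - PROMOTER_DOWNSTREAM
        assert hi == MINUS.tss + PROMOTER_UPSTREAM + 1

    def test_introns_are_exon_complement(self):
        assert PLUS.introns() == ((20300, 20700), (21000, 28000))

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", 100, 200, ((50, 150),))


class TestClassify:
    @pytest.fixture()
    def index(self):
        return GeneIndex([PLUS, MINUS])

    def test_promoter_inside_window(self, index):
        lab = classify_fragment("chr1", 20100, 20200, index)
        assert lab.location == "promoter"
        assert lab.gene_id == "gA"
        assert lab.tss_distance == 150  # midpoint downstream of TSS

    def test_promoter_has_precedence_over_exon(self, index):
        # fragment inside first exon but also inside TSS+5kb window
        assert classify_fragment("chr1", 20050, 20250, index).location == "promoter"

    def test_exon_beyond_promoter_window(self, index):
        assert classify_fragment("chr1", 29000, 29100, index).location == "exon"

    def test_intron_beyond_promoter_window(self, index):
        assert classify_fragment("chr1", 26000, 26100, index).location == "intron"

    def test_boundary_spans_junction(self, index):
        lab = classify_fragment("chr1", 27950, 28050, index)
        assert lab.location == "exon_intron_boundary"

    def test_intergenic_far_from_everything(self, index):
        lab = classify_fragment("chr1", 45000, 45100, index)
        assert lab.location == "intergenic"
        assert lab.gene_id is None

    def test_minus_strand_promoter_is_downstream_in_genome(self, index):
        # gB TSS at 71999; its promoter extends 5 kb towards lower coords
        assert classify_fragment("chr1", 67500, 67600, index).location == "promoter"
        assert classify_fragment("chr1", 61000, 61100, index).location == "exon"

    def test_unknown_chromosome_is_intergenic(self, index):
        assert classify_fragment("chr9", 0, 100, index).location == "intergenic"


class TestAnnotateCatalog:
    def test_empty_models_all_intergenic(self):
        cat = catalog_from_intervals([(0, 100), (500, 600)])
        out = annotate_catalog(cat, [])
        assert (out.location == "intergenic").all()
        assert out.gene_id.isna().all()

    def test_matches_brute_force_oracle(self, rng):
        starts = rng.integers(0, 90000, size=300)
        cat = catalog_from_intervals(
            [(int(s), int(s + rng.integers(40, 221))) for s in starts]
        )
        models = [PLUS, MINUS, GeneModel("gC", "chr1", "+", 40000, 47000, ((40000, 43000), (45000, 47000)))]
        out = annotate_catalog(cat, models)
        for row in cat.frame.itertuples():
            ref = brute_force_classify(row.chrom, row.start, row.end, models)
            assert out.loc[row.fragment_id, "location"] == ref.location
            got_gene = out.loc[row.fragment_id, "gene_id"]
            assert (got_gene if pd.notna(got_gene) else None) == ref.gene_id

    def test_invariant_under_model_order(self, rng):
        cat = catalog_from_intervals(
            [(int(s), int(s) + 100) for s in rng.integers(0, 80000, size=100)]
        )
        models = [PLUS, MINUS]
        a = annotate_catalog(cat, models)
        b = annotate_catalog(cat, models[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestLoaders:
    def test_bed12_two_blocks(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t1000\tmygene\t0\t+\t100\t1000\t0\t2\t200,300\t0,600\n")
        (model,) = load_gene_models(p)
        assert model.exons == ((100, 300), (700, 1000))
        assert model.introns() == ((300, 700),)
        assert model.tss == 100

    def test_bed12_minus_strand_tss(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t500\tg\t0\t-\t100\t500\t0\t1\t400\t0\n")
        (model,) = load_gene_models(p)
        assert model.tss == 499

    def test_gtf_longest_transcript_wins(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        attrs = 'gene_id "G1"; transcript_id "%s";'
        lines = [
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\t" + attrs % "t.short",
            "chr1\tsrc\texon\t101\t300\t.\t+\t.\t" + attrs % "t.long",
            "chr1\tsrc\texon\t401\t900\t.\t+\t.\t" + attrs % "t.long",
        ]
        gtf.write_text("\n".join(lines) + "\n")
        (model,) = load_gene_models(gtf)
        assert (model.start, model.end) == (100, 900)
        assert model.exons == ((100, 300), (400, 900))

    def test_label_invariant(self):
        with pytest.raises(ValueError):
            AnnotationLabel("intergenic", "G1", 0)
        with pytest.raises(ValueError):
            AnnotationLabel("exon", None, 0)
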