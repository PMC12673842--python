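"""Plot-model construction and the thin renderer."""

import random

import numpy as np
import pandas as pd
import pytest

from isoscope import classify, visualize
from isoscope.annotation import ExonRecord
from isoscope.errors import PlotModelError
from isoscope.visualize import (
    Mark,
    build_expression_profile_model,
    build_fc_profile_model,
    build_tx_context_model,
    render,
)


@pytest.fixture()
def gene_tx_rows(tx2gene):
    """Three isoforms of one gene: two significant, one not."""
    gene = tx2gene.frame.groupby("gene_name").size()
    gene = gene[gene >= 3].index[0]
    sub = tx2gene.frame.loc[tx2gene.frame["gene_name"] == gene].head(3)
    de = pd.DataFrame(
        {
            "transcript_id": list(sub["transcript_id"]),
            "log2fc": [2.0, -1.5, 0.2],
            "pvalue": [1e-4, 1e-3, 0.6],
            "qvalue": [1e-3, 1e-2, 0.7],
        }
    )
    return gene, classify.annotate_de_table(de, tx2gene)


class TestFcProfileModel:
    def test_bar_count_and_opacity_mapping(self, gene_tx_rows):
        gene, rows = gene_tx_rows
        gene_id = rows["gene_id"].iloc[0]
        gene_de = pd.DataFrame(
            {"gene_id": [gene_id], "log2fc": [0.1], "pvalue": [0.8], "qvalue": [0.9]}
        )
        model = build_fc_profile_model(gene, rows, gene_de)
        bars = [m for m in model.marks if m.mark_type == "bar"]
        assert len(bars) == 4  # n_isoforms + 1 gene bar
        low = [b for b in bars if b.opacity == visualize.NONSIG_OPACITY]
        # one non-significant isoform + the non-significant gene bar
        assert len(low) == 2
        assert {b.color_key for b in bars if b.color_key == "gene"} == {"gene"}

    def test_untested_gene_drawn_at_zero_with_distinct_key(self, gene_tx_rows):
        gene, rows = gene_tx_rows
        model = build_fc_profile_model(gene, rows, None)
        gene_bar = [m for m in model.marks if m.color_key == "gene_untested"]
        assert len(gene_bar) == 1
        assert gene_bar[0].y1 == 0.0

    def test_unknown_gene_is_an_error(self, gene_tx_rows):
        _, rows = gene_tx_rows
        with pytest.raises(PlotModelError, match="Nope"):
            build_fc_profile_model("Nope", rows)

    def test_two_contrasts_give_two_facets_of_full_bar_sets(self, gene_tx_rows):
        gene, rows = gene_tx_rows
        doubled = pd.concat(
            [rows.assign(contrast="c1"), rows.assign(contrast="c2")], ignore_index=True
        )
        model = build_fc_profile_model(gene, doubled)
        assert model.facets == ("c1", "c2")
        for facet in model.facets:
            bars = [m for m in model.marks if m.mark_type == "bar" and m.facet == facet]
            assert len(bars) == 4


class TestExpressionProfileModel:
    def _matrix(self):
        return pd.DataFrame(
            {
                "s1": [10.0, 5.0],
                "s2": [12.0, 6.0],
                "s3": [14.0, 7.0],
                "s4": [20.0, 5.0],
                "s5": [22.0, 6.0],
                "s6": [24.0, 7.0],
            },
            index=pd.Index(["txA", "txB"], name="transcript_id"),
        )

    def _groups(self):
        return {f"s{i}": ("ctrl" if i <= 3 else "case") for i in range(1, 7)}

    def test_means_and_sample_sd_whiskers(self):
        model = build_expression_profile_model("G", self._matrix(), self._groups())
        whiskers = [m for m in model.marks if m.mark_type == "whisker" and m.color_key == "txA"]
        ctrl = whiskers[0]
        # group ctrl of txA: mean 12, sample SD 2 -> whisker spans [10, 14]
        assert (ctrl.y0, ctrl.y1) == (10.0, 14.0)
        lines = [m for m in model.marks if m.mark_type == "line"]
        assert len(lines) == 2  # one polyline per isoform
        assert lines[0].points[0] == (0.0, 12.0)

    def test_single_sample_group_gives_degenerate_whisker(self):
        matrix = self._matrix()[["s1", "s4"]]
        groups = {"s1": "ctrl", "s4": "case"}
        model = build_expression_profile_model("G", matrix, groups)
        for w in (m for m in model.marks if m.mark_type == "whisker"):
            assert w.y0 == w.y1

    def test_unmapped_sample_is_an_error(self):
        groups = self._groups()
        groups.pop("s3")
        with pytest.raises(PlotModelError, match="s3"):
            build_expression_profile_model("G", self._matrix(), groups)

    def test_whisker_halflength_equals_independent_sample_sd(self):
        rng = np.random.default_rng(12)
        matrix = pd.DataFrame(
            rng.lognormal(2, 1, size=(4, 10)),
            index=pd.Index([f"tx{i}" for i in range(4)], name="transcript_id"),
            columns=[f"s{i}" for i in range(10)],
        )
        groups = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        model = build_expression_profile_model("G", matrix, groups)
        for tx_i, tx in enumerate(matrix.index):
            whiskers = [m for m in model.marks if m.mark_type == "whisker" and m.color_key == tx]
            for gi, g in enumerate(["a", "b"]):
                cols = [s for s, grp in groups.items() if grp == g]
                sd = float(np.std(matrix.loc[tx, cols], ddof=1))
                half = (whiskers[gi].y1 - whiskers[gi].y0) / 2
                assert half == pytest.approx(sd, abs=1e-12)


class TestTxContextModel:
    def _exons(self):
        mk = lambda tx, s, e, n, strand: ExonRecord(tx, "G", "chr1", s, e, strand, n)
        return [
            mk("T_plus", 100, 200, 1, "+"),
            mk("T_plus", 300, 400, 2, "+"),
            mk("T_minus", 150, 220, 2, "-"),
            mk("T_minus", 500, 560, 1, "-"),
            mk("T_single", 900, 980, 1, "+"),
        ]

    def test_exon_rects_and_gap_segments(self):
        model = build_tx_context_model(self._exons())
        rects = [m for m in model.marks if m.mark_type == "rect"]
        segments = [m for m in model.marks if m.mark_type == "segment"]
        assert len(rects) == 5  # one per exon
        assert len(segments) == 2  # sum over transcripts of (n_exons - 1)
        gap = [s for s in segments if s.row == 0][0]
        assert (gap.x0, gap.x1) == (200.0, 300.0)

    def test_rows_ordered_by_genomic_start_regardless_of_strand(self):
        model = build_tx_context_model(self._exons())
        labels = sorted(
            (m for m in model.marks if m.mark_type == "label"), key=lambda m: m.row
        )
        names = [l.text.split(" ")[0] for l in labels]
        assert names == ["T_plus", "T_minus", "T_single"]

    def test_row_order_invariant_under_input_shuffling(self):
        exons = self._exons()
        shuffled = exons[:]
        random.Random(3).shuffle(shuffled)
        a = build_tx_context_model(exons)
        b = build_tx_context_model(shuffled)
        key = lambda m: (m.mark_type, m.row, m.x0, m.x1)
        assert sorted(a.marks, key=key) == sorted(b.marks, key=key)

    def test_single_exon_transcript_has_no_segment(self):
        model = build_tx_context_model([self._exons()[4]])
        assert model.counts() == {"rect": 1, "label": 1}

    def test_multi_chromosome_and_empty_inputs_rejected(self):
        exons = self._exons()
        other = ExonRecord("T_x", "G", "chr2", 10, 20, "+", 1)
        with pytest.raises(PlotModelError, match="chromosome"):
            build_tx_context_model(exons + [other])
        with pytest.raises(PlotModelError, match="no exon"):
            build_tx_context_model([])


class TestRender:
    def test_same_model_renders_to_identical_svg_bytes(self, gene_tx_rows, tmp_path):
        gene, rows = gene_tx_rows
        model = build_fc_profile_model(gene, rows)
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render(model, a)
        render(model, b)
        assert a.read_bytes() == b.read_bytes()

    def test_png_and_pdf_smoke(self, gene_tx_rows, tmp_path):
        gene, rows = gene_tx_rows
        model = build_fc_profile_model(gene, rows)
        for name in ("p.png", "p.pdf"):
            out = render(model, tmp_path / name)
            assert out.stat().st_size > 0
        # rendering never mutates the model
        assert model == build_fc_profile_model(gene, rows)

    def test_zero_mark_model_rejected(self, tmp_path):
        model = visualize.PlotModel(kind="fc_profile", marks=())
        with pytest.raises(PlotModelError, match="zero marks"):
            render(model, tmp_path / "x.png")

    def test_unsupported_format_rejected(self, gene_tx_rows, tmp_path):
        gene, rows = gene_tx_rows
        model = build_fc_profile_model(gene, rows)
        with pytest.raises(PlotModelError, match="format"):
            render(model, tmp_path / "x.bmp")


def test_mark_geometry_must_be_finite_and_opacity_in_range():
    with pytest.raises(PlotModelError):
        Mark("bar", x0=float("nan"))
    with pytest.raises(PlotModelError):
        Mark("bar", opacity=0.0)
    with pytest.raises(PlotModelError):
        Mark("squiggle")
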