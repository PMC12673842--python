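"""Declarative plot models for the three transcript-level displays.

Plot *models* — ordered lists of geometric marks in data units — are the
tested surface; rendering is a thin, deterministic matplotlib pass that never
recomputes a statistic.  The three model kinds:

``fc_profile``
    One bar per isoform plus one for the gene, height = log2 fold-change,
    colored by biotype category; non-significant bars are drawn at reduced
    opacity.  Faceted per contrast when multiple contrasts are present.
``expression_profile``
    Per-isoform lines connecting group-mean TPM, with whiskers spanning
    mean ± 1 sample standard deviation per (isoform, group).
``tx_context``
    Genomic context: one row per transcript, exons as rectangles, introns as
    segments across the exact inter-exon gap.  Rows are ordered by genomic
    start, so sense-strand models read left→right and antisense-strand
    models' 5' ends sit at the right.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord, TxToGeneTable, strip_version
from .errors import PlotModelError

#: Opacity of bars that failed the significance cut.
NONSIG_OPACITY = 0.3

#: Reserved color keys for the gene-level bar.
GENE_KEY = "gene"
GENE_UNTESTED_KEY = "gene_untested"

_MARK_TYPES = ("bar", "line", "whisker", "rect", "segment", "label")
_RENDER_FORMATS = ("png", "svg", "pdf")


@dataclass(frozen=True)
class Mark:
    """One geometric mark in data units.

    ``bar``/``rect`` use the (x0, x1, y0, y1) box; ``segment``/``whisker``
    use (x0, y0)→(x1, y1); ``line`` uses ``points`` (a polyline); ``label``
    uses (x0, y0) and ``text``.  All geometry must be finite.
    """

    mark_type: str
    x0: float = 0.0
    x1: float = 0.0
    y0: float = 0.0
    y1: float = 0.0
    points: tuple[tuple[float, float], ...] = ()
    color_key: str = "default"
    opacity: float = 1.0
    row: int = 0
    text: str = ""
    facet: str | None = None

    def __post_init__(self):
        if self.mark_type not in _MARK_TYPES:
            raise PlotModelError(f"unknown mark type {self.mark_type!r}")
        coords = [self.x0, self.x1, self.y0, self.y1]
        coords += [c for pt in self.points for c in pt]
        if not all(math.isfinite(c) for c in coords):
            raise PlotModelError(f"non-finite geometry in {self.mark_type} mark")
        if not (0 < self.opacity <= 1):
            raise PlotModelError(f"opacity must be in (0, 1], got {self.opacity}")


@dataclass(frozen=True)
class PlotModel:
    """A backend-agnostic plot: a kind, ordered marks, facets, and a legend."""

    kind: str
    marks: tuple[Mark, ...]
    facets: tuple[str, ...] = ()
    legend: tuple[tuple[str, str], ...] = ()  # (color_key, label) pairs
    title: str = ""

    def __post_init__(self):
        rows = sorted({m.row for m in self.marks})
        if rows and rows != list(range(len(rows))):
            raise PlotModelError(f"row indices must be contiguous from 0, got {rows}")

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for mark in self.marks:
            out[mark.mark_type] = out.get(mark.mark_type, 0) + 1
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "title": self.title,
            "facets": list(self.facets),
            "legend": [list(e) for e in self.legend],
            "marks": [asdict(m) for m in self.marks],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_fc_profile_model(
    gene_name: str,
    annotated_tx_rows: pd.DataFrame,
    annotated_gene_rows: pd.DataFrame | None = None,
) -> PlotModel:
    """Fold-change profile: one bar per isoform plus one for the gene.

    ``annotated_tx_rows`` is the output of ``classify.annotate_de_table``
    (flagged).  ``annotated_gene_rows`` is the gene-level DE table; when the
    gene is absent (or no table given) its bar is drawn at 0 under the
    distinct ``gene_untested`` key.  Significant bars get opacity 1.0,
    non-significant ones 0.3; one facet per contrast.
    """
    rows = annotated_tx_rows.loc[annotated_tx_rows["gene_name"] == gene_name]
    if rows.empty:
        raise PlotModelError(f"gene {gene_name!r} has no transcript rows")

    if "contrast" in rows.columns and rows["contrast"].notna().any():
        facet_values = [str(c) for c in pd.unique(rows["contrast"].dropna())]
    else:
        facet_values = [None]

    gene_keys = {strip_version(str(g)) for g in rows["gene_id"].dropna()}

    marks: list[Mark] = []
    legend_keys: dict[str, str] = {}
    for facet in facet_values:
        if facet is None:
            sub = rows
        else:
            sub = rows.loc[rows["contrast"].astype(str) == facet]
        sub = sub.sort_values(["transcript_name", "transcript_id"], kind="mergesort")
        x = 0
        for r in sub.itertuples():
            opacity = 1.0 if bool(r.is_significant) else NONSIG_OPACITY
            key = str(r.category)
            legend_keys.setdefault(key, key)
            marks.append(
                Mark(
                    "bar",
                    x0=x - 0.4,
                    x1=x + 0.4,
                    y0=0.0,
                    y1=float(r.log2fc),
                    color_key=key,
                    opacity=opacity,
                    text=str(r.transcript_name),
                    facet=facet,
                )
            )
            x += 1
        gene_row = _find_gene_row(annotated_gene_rows, gene_keys, facet)
        if gene_row is None:
            marks.append(
                Mark(
                    "bar",
                    x0=x - 0.4,
                    x1=x + 0.4,
                    y0=0.0,
                    y1=0.0,
                    color_key=GENE_UNTESTED_KEY,
                    opacity=NONSIG_OPACITY,
                    text=gene_name,
                    facet=facet,
                )
            )
            legend_keys.setdefault(GENE_UNTESTED_KEY, "gene (untested)")
        else:
            gfc, gsig = gene_row
            marks.append(
                Mark(
                    "bar",
                    x0=x - 0.4,
                    x1=x + 0.4,
                    y0=0.0,
                    y1=gfc,
                    color_key=GENE_KEY,
                    opacity=1.0 if gsig else NONSIG_OPACITY,
                    text=gene_name,
                    facet=facet,
                )
            )
            legend_keys.setdefault(GENE_KEY, "gene")
    return PlotModel(
        kind="fc_profile",
        marks=tuple(marks),
        facets=tuple(f for f in facet_values if f is not None),
        legend=tuple(sorted(legend_keys.items())),
        title=gene_name,
    )


def _find_gene_row(
    gene_rows: pd.DataFrame | None, gene_keys: set[str], facet: str | None
) -> tuple[float, bool] | None:
    """(log2fc, is_significant) of the gene in one contrast, or None if untested."""
    if gene_rows is None or gene_rows.empty or not gene_keys:
        return None
    from .classify import flag_gene_significance

    sub = gene_rows
    if facet is not None and "contrast" in sub.columns:
        sub = sub.loc[sub["contrast"].astype(str) == facet]
    sub = sub.loc[sub["gene_id"].map(lambda g: strip_version(str(g))).isin(gene_keys)]
    if sub.empty:
        return None
    if "is_significant" not in sub.columns:
        sub = flag_gene_significance(sub)
    row = sub.iloc[0]
    return float(row["log2fc"]), bool(row["is_significant"])


def build_expression_profile_model(
    gene_name: str,
    tpm_matrix: pd.DataFrame,
    sample_groups: Mapping[str, str],
    tx_to_gene: TxToGeneTable | None = None,
) -> PlotModel:
    """Expression profile: group-mean TPM lines with ±1 SD whiskers.

    ``tpm_matrix`` has transcripts as rows and samples as columns.  When an
    annotation dictionary is given the matrix is restricted to the gene's
    isoforms; otherwise every row is taken as an isoform of the gene.  Group
    order follows first appearance in ``sample_groups``; the standard
    deviation is the sample SD (ddof=1; 0 for single-sample groups).
    """
    unmapped = [s for s in tpm_matrix.columns if s not in sample_groups]
    if unmapped:
        raise PlotModelError(f"sample(s) missing from the group map: {unmapped}")
    if tx_to_gene is not None:
        wanted = {
            strip_version(t)
            for t, g in zip(tx_to_gene.frame["transcript_id"], tx_to_gene.frame["gene_name"])
            if g == gene_name
        }
        keep = [t for t in tpm_matrix.index if strip_version(str(t)) in wanted]
        matrix = tpm_matrix.loc[keep]
    else:
        matrix = tpm_matrix
    if matrix.empty:
        raise PlotModelError(f"no isoforms of gene {gene_name!r} in the TPM matrix")

    groups: list[str] = []
    for sample in tpm_matrix.columns:
        g = sample_groups[sample]
        if g not in groups:
            groups.append(g)
    cols_by_group = {
        g: [s for s in tpm_matrix.columns if sample_groups[s] == g] for g in groups
    }

    marks: list[Mark] = []
    legend: dict[str, str] = {}
    for tx_id, values in matrix.iterrows():
        key = str(tx_id)
        legend.setdefault(key, key)
        pts = []
        for gi, g in enumerate(groups):
            obs = values[cols_by_group[g]].to_numpy(float)
            mean = float(np.mean(obs))
            sd = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
            pts.append((float(gi), mean))
            marks.append(
                Mark(
                    "whisker",
                    x0=float(gi),
                    x1=float(gi),
                    y0=mean - sd,
                    y1=mean + sd,
                    color_key=key,
                )
            )
        marks.append(Mark("line", points=tuple(pts), color_key=key, text=key))
    return PlotModel(
        kind="expression_profile",
        marks=tuple(marks),
        legend=tuple(sorted(legend.items())),
        title=gene_name,
    )


def build_tx_context_model(
    exon_records: Sequence[ExonRecord],
    tx_to_gene: TxToGeneTable | None = None,
) -> PlotModel:
    """Genomic-context model: exon rectangles and intron segments per transcript.

    One row per transcript, ordered by genomic start (ascending), which makes
    plus-strand transcript models start at the left and minus-strand models'
    5' ends sit at the right.  Intron segments span the exact gap between
    consecutive exons (end of exon *i* to start of exon *i+1*, exons sorted
    by start).  Labels carry the transcript name, biotype (when resolvable)
    and strand.  Requires a non-empty, single-chromosome input.
    """
    if not exon_records:
        raise PlotModelError("no exon records given")
    chroms = {e.chrom for e in exon_records}
    if len(chroms) > 1:
        raise PlotModelError(f"exons span more than one chromosome: {sorted(chroms)}")

    by_tx: dict[str, list[ExonRecord]] = {}
    for exon in exon_records:
        by_tx.setdefault(exon.transcript_id, []).append(exon)
    order = sorted(
        by_tx, key=lambda t: (min(e.start for e in by_tx[t]), t)
    )

    marks: list[Mark] = []
    legend: dict[str, str] = {}
    for row, tx_id in enumerate(order):
        exons = sorted(by_tx[tx_id], key=lambda e: e.start)
        strand = exons[0].strand
        name, biotype = tx_id, None
        if tx_to_gene is not None:
            rec = tx_to_gene.lookup(tx_id)
            if rec is not None:
                name, biotype = str(rec["transcript_name"]), str(rec["transcript_type"])
        key = biotype if biotype else "transcript"
        legend.setdefault(key, key)
        for exon in exons:
            marks.append(
                Mark(
                    "rect",
                    x0=float(exon.start),
                    x1=float(exon.end),
                    y0=row - 0.3,
                    y1=row + 0.3,
                    color_key=key,
                    row=row,
                )
            )
        for left, right in zip(exons, exons[1:]):
            marks.append(
                Mark(
                    "segment",
                    x0=float(left.end),
                    x1=float(right.start),
                    y0=float(row),
                    y1=float(row),
                    color_key=key,
                    row=row,
                )
            )
        label = f"{name} ({biotype}, {strand})" if biotype else f"{name} ({strand})"
        marks.append(
            Mark(
                "label",
                x0=float(exons[0].start),
                y0=float(row),
                text=label,
                color_key=key,
                row=row,
            )
        )
    return PlotModel(
        kind="tx_context",
        marks=tuple(marks),
        legend=tuple(sorted(legend.items())),
        title=next(iter(chroms)),
    )


# ---------------------------------------------------------------------------
# rendering

_PALETTE = {
    "protein_coding": "#1b9e77",
    "retained_intron": "#d95f02",
    "nonsense_mediated_decay": "#7570b3",
    "CDS_undefined": "#e7298a",
    "lncRNA": "#66a61e",
    "other": "#a6761d",
    "unannotated": "#999999",
    GENE_KEY: "#333333",
    GENE_UNTESTED_KEY: "#bbbbbb",
    "default": "#1f77b4",
}

_FALLBACK_CYCLE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def _color_for(key: str, cycle_index: dict[str, str]) -> str:
    if key in _PALETTE:
        return _PALETTE[key]
    if key not in cycle_index:
        cycle_index[key] = _FALLBACK_CYCLE[len(cycle_index) % len(_FALLBACK_CYCLE)]
    return cycle_index[key]


def render(model: PlotModel, path: str | Path, fmt: str | None = None) -> Path:
    """Render a plot model to png/svg/pdf.

    A pure function of the model: no statistics are recomputed here, and SVG
    output is stripped of timestamps/hash salts so identical models render to
    identical bytes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".") or "png").lower()
    if fmt not in _RENDER_FORMATS:
        raise PlotModelError(f"unsupported format {fmt!r}; use one of {_RENDER_FORMATS}")
    if not model.marks:
        raise PlotModelError("cannot render a model with zero marks")

    facet_values: list[str | None] = list(model.facets) or [None]
    cycle: dict[str, str] = {}
    with plt.rc_context({"svg.hashsalt": "isoscope"}):
        fig, axes = plt.subplots(
            1, len(facet_values), figsize=(4.5 * len(facet_values), 3.5), squeeze=False
        )
        for ax, facet in zip(axes[0], facet_values):
            for mark in model.marks:
                if facet is not None and mark.facet is not None and mark.facet != facet:
                    continue
                color = _color_for(mark.color_key, cycle)
                if mark.mark_type in ("bar", "rect"):
                    ax.add_patch(
                        plt.Rectangle(
                            (min(mark.x0, mark.x1), min(mark.y0, mark.y1)),
                            abs(mark.x1 - mark.x0),
                            abs(mark.y1 - mark.y0),
                            facecolor=color,
                            alpha=mark.opacity,
                        )
                    )
                elif mark.mark_type in ("segment", "whisker"):
                    ax.plot(
                        [mark.x0, mark.x1], [mark.y0, mark.y1],
                        color=color, alpha=mark.opacity, linewidth=1.2,
                    )
                elif mark.mark_type == "line":
                    xs = [p[0] for p in mark.points]
                    ys = [p[1] for p in mark.points]
                    ax.plot(xs, ys, color=color, alpha=mark.opacity, marker="o", markersize=3)
                elif mark.mark_type == "label":
                    ax.annotate(
                        mark.text, (mark.x0, mark.y0),
                        fontsize=7, va="bottom", color="#222222",
                    )
            ax.relim()
            ax.autoscale_view()
            ax.set_title(facet if facet is not None else model.title, fontsize=9)
        handles = [
            plt.Line2D([], [], color=_color_for(k, cycle), label=lbl, linewidth=4)
            for k, lbl in model.legend
        ]
        if handles:
            axes[0][-1].legend(handles=handles, fontsize=6, loc="best")
        fig.tight_layout()
        if fmt == "svg":
            fig.savefig(path, format=fmt, metadata={"Date": None})
        elif fmt == "pdf":
            fig.savefig(path, format=fmt, metadata={"CreationDate": None})
        else:
            fig.savefig(path, format=fmt)
        plt.close(fig)
    return path
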