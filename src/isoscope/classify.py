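"""Differential-expression classification and isoform-switch candidate detection.

Joins transcript-level DE results to the annotation dictionary, applies
biotype-aware significance thresholds, drops Terminus-collapsed clusters, and
extracts the DET-without-DEG table: significantly differentially expressed
transcripts whose parent genes are *not* differentially expressed — the
signature of an isoform switch or transcript-level regulatory event.

Significance thresholds differ by molecular type.  mRNA-class isoforms
(protein_coding, retained_intron, nonsense-mediated decay, CDS-undefined —
all products of coding loci) require an absolute log2 fold-change of at
least 1 with q < 0.05; lncRNA isoforms, being expressed at lower levels,
use the relaxed cut of 0.5.  Boundary semantics are exact: the fold-change
bound is inclusive (``>=``), the q-value bound strict (``<``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .annotation import TxToGeneTable, strip_version
from .biotypes import UNANNOTATED, biotype_category

log = logging.getLogger(__name__)

#: Required columns of a DE input table (transcript- or gene-level).
DE_COLUMNS = ("log2fc", "pvalue", "qvalue")

#: Tri-state gene significance labels.
GENE_SIG_YES, GENE_SIG_NO, GENE_SIG_UNTESTED = "yes", "no", "untested"

#: Column order of the exported switch-candidate table.
SWITCH_COLUMNS = [
    "transcript_id",
    "gene_id",
    "gene_name",
    "transcript_name",
    "biotype",
    "log2fc",
    "qvalue",
    "gene_log2fc",
    "gene_qvalue",
    "gene_is_significant",
    "contrast",
]


@dataclass(frozen=True)
class ThresholdRule:
    """Significance cut for one biotype category."""

    min_abs_log2fc: float
    max_qvalue: float

    def __post_init__(self):
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_qvalue <= 1):
            raise ValueError("max_qvalue must be in (0, 1]")


def _default_rules() -> dict[str, ThresholdRule]:
    mrna = ThresholdRule(1.0, 0.05)
    return {
        "protein_coding": mrna,
        "retained_intron": mrna,
        "nonsense_mediated_decay": mrna,
        "CDS_undefined": mrna,
        "lncRNA": ThresholdRule(0.5, 0.05),
        "other": mrna,
    }


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-category significance thresholds; unknown categories fall to ``other``.

    The defaults encode the mRNA rule (|log2FC| >= 1, q < 0.05) for all
    coding-locus categories and the relaxed lncRNA rule (|log2FC| >= 0.5,
    q < 0.05).  Gene-level tests always use the coding-locus rule.
    """

    rules: dict[str, ThresholdRule] = field(default_factory=_default_rules)

    def for_category(self, category: str) -> ThresholdRule:
        return self.rules.get(category, self.rules["other"])

    @property
    def gene_rule(self) -> ThresholdRule:
        return self.rules.get("protein_coding", self.rules["other"])

    def with_rule(self, category: str, min_abs_log2fc: float, max_qvalue: float) -> "ThresholdPolicy":
        rules = dict(self.rules)
        rules[category] = ThresholdRule(min_abs_log2fc, max_qvalue)
        return ThresholdPolicy(rules)


def read_de_table(
    path: str | Path | IO[str], feature_col: str = "transcript_id"
) -> pd.DataFrame:
    """Read a DE TSV (feature_id, log2fc, pvalue, qvalue[, contrast])."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in (feature_col, *DE_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"DE table missing required column(s): {missing}")
    return frame


def remove_collapsed_clusters(
    de_rows: pd.DataFrame,
    cluster_membership: Mapping[str, str] | pd.DataFrame,
    feature_col: str = "transcript_id",
) -> pd.DataFrame:
    """Drop transcripts that Terminus collapsed into clusters.

    Near-identical isoforms receive statistically indistinguishable read
    assignments; removing their cluster members before DE interpretation
    avoids spurious transcript-level calls.  Matching is version-insensitive.
    Membership entries naming transcripts absent from the table are ignored
    with a warning; an empty membership is a no-op.
    """
    if isinstance(cluster_membership, pd.DataFrame):
        ids = cluster_membership["transcript_id"]
    else:
        ids = pd.Series(list(cluster_membership), dtype=object)
    clustered = {strip_version(str(t)) for t in ids}
    if not clustered:
        return de_rows
    keys = de_rows[feature_col].map(strip_version)
    mask = keys.isin(clustered)
    absent = clustered - set(keys)
    if absent:
        log.warning(
            "%d cluster member(s) not present in the DE table (ignored): %s",
            len(absent),
            sorted(absent)[:10],
        )
    kept = de_rows.loc[~mask].reset_index(drop=True)
    log.info(
        "removed %d collapsed-cluster row(s), kept %d", int(mask.sum()), len(kept)
    )
    return kept


def flag_significance(
    rows: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
    category_col: str = "category",
) -> pd.DataFrame:
    """Set ``is_significant`` from (|log2fc|, qvalue) under per-category rules.

    ``is_significant = (|log2fc| >= min_abs_log2fc) AND (qvalue < max_qvalue)``
    for the row's category; missing q-values flag the row not significant and
    are counted in a warning.  Returns a copy.
    """
    policy = policy or ThresholdPolicy()
    out = rows.copy()
    if category_col not in out.columns:
        out[category_col] = "other"
    cats = out[category_col].fillna("other")
    fc_min = cats.map(lambda c: policy.for_category(c).min_abs_log2fc).to_numpy(float)
    q_max = cats.map(lambda c: policy.for_category(c).max_qvalue).to_numpy(float)
    log2fc = pd.to_numeric(out["log2fc"], errors="coerce").to_numpy(float)
    qvalue = pd.to_numeric(out["qvalue"], errors="coerce").to_numpy(float)
    n_missing = int(np.isnan(qvalue).sum())
    if n_missing:
        log.warning("%d row(s) with missing q-value flagged not significant", n_missing)
    with np.errstate(invalid="ignore"):
        sig = (np.abs(log2fc) >= fc_min) & (qvalue < q_max)
    sig &= ~np.isnan(qvalue) & ~np.isnan(log2fc)
    out["is_significant"] = sig
    return out


def annotate_de_table(
    de_rows: pd.DataFrame,
    tx_to_gene: TxToGeneTable,
    policy: ThresholdPolicy | None = None,
    biotype_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join a transcript DE table to the annotation dictionary and flag it.

    The join uses the version-stripped index; transcripts without a dictionary
    match get biotype category ``unannotated`` (significance still computed
    under the ``other`` rule).  An unmatched fraction above 50% triggers a
    loud warning — it usually means the DE table and reference disagree.
    """
    dict_frame = tx_to_gene.frame.copy()
    dict_frame["_key"] = dict_frame["transcript_id"].map(strip_version)
    dict_frame = dict_frame.drop_duplicates("_key").set_index("_key")

    out = de_rows.copy()
    keys = out["transcript_id"].map(strip_version)
    joined = dict_frame.reindex(keys)
    out["gene_id"] = joined["gene_id"].to_numpy()
    out["gene_name"] = joined["gene_name"].to_numpy()
    out["transcript_name"] = joined["transcript_name"].to_numpy()
    out["biotype"] = joined["transcript_type"].to_numpy()
    matched = out["gene_id"].notna()
    out["category"] = [
        biotype_category(b, biotype_map) if isinstance(b, str) else UNANNOTATED
        for b in out["biotype"]
    ]
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        frac = n_unmatched / max(len(out), 1)
        msg = "%d/%d DE transcript(s) not found in the annotation dictionary"
        if frac > 0.5:
            log.warning(msg + " — is this the right reference?", n_unmatched, len(out))
        else:
            log.info(msg, n_unmatched, len(out))
    return flag_significance(out, policy)


def flag_gene_significance(
    gene_rows: pd.DataFrame, policy: ThresholdPolicy | None = None
) -> pd.DataFrame:
    """Flag a gene-level DE table with the coding-locus default thresholds."""
    policy = policy or ThresholdPolicy()
    out = gene_rows.copy()
    rule = policy.gene_rule
    single = ThresholdPolicy({"other": rule})
    out = flag_significance(out, single, category_col="_gene_category")
    return out.drop(columns=["_gene_category"])


def attach_gene_significance(
    tx_rows: pd.DataFrame,
    gene_rows: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
) -> pd.DataFrame:
    """Annotate flagged transcript rows with their gene's DE outcome.

    Adds ``gene_log2fc``, ``gene_qvalue`` and the tri-state
    ``gene_is_significant`` (``yes`` / ``no`` / ``untested``).  When both
    tables carry a ``contrast`` column the join is per contrast.
    """
    genes = flag_gene_significance(gene_rows, policy)
    genes = genes.rename(
        columns={"log2fc": "gene_log2fc", "qvalue": "gene_qvalue", "is_significant": "_gene_sig"}
    )
    genes["_gkey"] = genes["gene_id"].map(lambda g: strip_version(str(g)))
    out = tx_rows.copy()
    out["_gkey"] = out["gene_id"].map(lambda g: strip_version(str(g)) if isinstance(g, str) else "")

    join_cols = ["_gkey"]
    if "contrast" in out.columns and "contrast" in genes.columns:
        join_cols.append("contrast")
    keep = join_cols + ["gene_log2fc", "gene_qvalue", "_gene_sig"]
    genes_small = genes[keep].drop_duplicates(join_cols)
    out = out.merge(genes_small, on=join_cols, how="left")
    out["gene_is_significant"] = np.where(
        out["_gene_sig"].isna(),
        GENE_SIG_UNTESTED,
        np.where(out["_gene_sig"].astype("boolean").fillna(False), GENE_SIG_YES, GENE_SIG_NO),
    )
    return out.drop(columns=["_gkey", "_gene_sig"])


def det_without_deg(
    tx_rows: pd.DataFrame,
    gene_rows: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
) -> pd.DataFrame:
    """Extract isoform-switch candidates: significant transcripts of non-DE genes.

    ``tx_rows`` must be the annotated + flagged transcript table
    (:func:`annotate_de_table`); ``gene_rows`` is the raw gene-level DE table
    (gene_id, log2fc, pvalue, qvalue[, contrast]).  A transcript whose gene
    was never tested at gene level is kept, flagged ``untested``, so users
    can filter on the tri-state.  Operates per contrast when contrasts are
    present in both tables.
    """
    if "is_significant" not in tx_rows.columns:
        raise ValueError("tx_rows must be flagged first (run annotate_de_table)")
    full = attach_gene_significance(tx_rows, gene_rows, policy)
    candidates = full.loc[
        full["is_significant"] & (full["gene_is_significant"] != GENE_SIG_YES)
    ].reset_index(drop=True)
    if "contrast" not in candidates.columns:
        candidates["contrast"] = pd.NA
    cols = [c for c in SWITCH_COLUMNS if c in candidates.columns]
    return candidates[cols]
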