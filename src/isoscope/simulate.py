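"""Synthetic GENCODE-like fixtures with planted, fully recorded structure.

Generates everything the pipeline consumes — reference GTF + transcript-FASTA
headers, transcript/gene DE tables, a TPM matrix with a sample→group map, and
a gene-level GMT database — emulating the shape of a bulk case-vs-control
RNA-seq study at desk scale.  Truth tables are first-class outputs: every
planted attribute (biotypes, switch transcripts, the planted gene set) is
recorded so downstream checks never re-derive the signal from the data.

Planted structure:

* *switch genes*: genes where exactly one isoform is strongly differentially
  expressed (positive log2FC at or above the configured effect size, q < 0.01)
  while the gene-level row is null (log2FC ≈ 0, q > 0.5) — the
  DET-without-DEG signature.
* *planted gene set*: one GMT set composed of the switch genes, whose
  protein-coding transcripts therefore occupy the top ranks of the
  fold-change-ranked list.

Null rows draw log2FC ~ Normal(0, 0.2) and q uniform on (0.05, 1], which
keeps chance significance off the q boundary by construction; boundary
behavior is exercised separately with hand-written rows.  All outputs are
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import ExonRecord, TranscriptRecord, write_gtf


def _default_biotype_proportions() -> dict[str, float]:
    # roughly GENCODE-like mix over the categories the workflow stratifies
    return {
        "protein_coding": 0.45,
        "lncRNA": 0.20,
        "retained_intron": 0.15,
        "nonsense_mediated_decay": 0.10,
        "protein_coding_CDS_not_defined": 0.10,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a small two-group bulk RNA-seq comparison: 60 genes with
    2–4 annotated isoforms each, 20 planted switch genes with a log2FC-2
    isoform effect, 20 gene sets of 10–50 genes (one planted), and 5 samples
    per group.  ``seed`` is mandatory.
    """

    n_genes: int = 60
    transcripts_per_gene: tuple[int, int] = (2, 4)
    biotype_proportions: dict[str, float] = field(
        default_factory=_default_biotype_proportions
    )
    n_switch_genes: int = 20
    switch_effect: float = 2.0  # planted |log2FC| floor for the switch isoform
    n_gene_sets: int = 20
    planted_set_fraction: float = 1.0  # fraction of planted-set members that are switch genes
    samples_per_group: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_switch_genes < 0 or self.n_gene_sets < 0:
            raise ValueError("counts must be non-negative (n_genes >= 1)")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype proportions must sum to 1, got {total}")
        lo, hi = self.transcripts_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("transcripts_per_gene must be an increasing range >= 1")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if not (0 < self.planted_set_fraction <= 1):
            raise ValueError("planted_set_fraction must be in (0, 1]")


PLANTED_SET_NAME = "PLANTED_SWITCH_SET"


class SimulatedAnnotation(NamedTuple):
    gtf_text: str
    fasta_text: str
    truth: pd.DataFrame  # one row per transcript
    transcripts: list  # TranscriptRecord
    exons: list  # ExonRecord


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Simulate a GENCODE-like reference: GTF, FASTA headers, truth table.

    Genes are placed on two synthetic chromosomes with alternating strands;
    each transcript gets 1–8 non-overlapping exons, and FASTA header lengths
    equal the exon-length sums by construction.
    """
    rng = np.random.default_rng(config.seed)
    biotypes = sorted(config.biotype_proportions)
    probs = np.array([config.biotype_proportions[b] for b in biotypes])

    transcripts: list[TranscriptRecord] = []
    exons: list[ExonRecord] = []
    truth_rows: list[dict] = []
    cursors = {"chrS1": 1000, "chrS2": 1000}
    tx_counter = 0
    lo, hi = config.transcripts_per_gene
    for gi in range(config.n_genes):
        chrom = "chrS1" if gi % 2 == 0 else "chrS2"
        strand = "+" if (gi // 2) % 2 == 0 else "-"
        gene_id = f"SIMG{gi + 1:05d}.1"
        gene_name = f"GENE{gi + 1:03d}"
        gene_start = cursors[chrom]
        n_tx = int(rng.integers(lo, hi + 1))
        gene_span_end = gene_start
        for ti in range(n_tx):
            tx_counter += 1
            tx_id = f"SIMT{tx_counter:05d}.1"
            tx_name = f"{gene_name}-{201 + ti}"
            biotype = biotypes[int(rng.choice(len(biotypes), p=probs))]
            n_exons = int(rng.integers(1, 9))
            # transcripts of the same gene share a neighborhood but may shift
            pos = gene_start + int(rng.integers(0, 200))
            tx_exons: list[tuple[int, int]] = []
            for _ in range(n_exons):
                length = int(rng.integers(50, 301))
                tx_exons.append((pos, pos + length - 1))
                pos += length + int(rng.integers(50, 501))  # intron gap
            # exon numbering is 5'->3': genomic order on +, reversed on -
            numbered = list(enumerate(tx_exons, start=1))
            if strand == "-":
                numbered = [
                    (n_exons - i + 1, span) for i, span in numbered
                ]
            for number, (start, end) in numbered:
                exons.append(
                    ExonRecord(
                        transcript_id=tx_id,
                        gene_name=gene_name,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        exon_number=number,
                    )
                )
            length_sum = sum(e - s + 1 for s, e in tx_exons)
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    transcript_name=tx_name,
                    gene_name=gene_name,
                    length=length_sum,
                    biotype=biotype,
                )
            )
            truth_rows.append(
                {
                    "transcript_id": tx_id,
                    "gene_id": gene_id,
                    "gene_name": gene_name,
                    "transcript_name": tx_name,
                    "chrom": chrom,
                    "strand": strand,
                    "n_exons": n_exons,
                    "length": length_sum,
                    "biotype": biotype,
                }
            )
            gene_span_end = max(gene_span_end, tx_exons[-1][1])
        cursors[chrom] = gene_span_end + int(rng.integers(5_000, 10_000))

    gtf_text = write_gtf(transcripts, exons, source="sim")
    fasta_lines = []
    for t in transcripts:
        fasta_lines.append(
            f">{t.transcript_id}|{t.gene_id}|-|-|{t.transcript_name}|{t.gene_name}|"
            f"{t.length}|{t.biotype}|"
        )
        fasta_lines.append("N" * 60)
    fasta_text = "\n".join(fasta_lines) + "\n"
    truth = pd.DataFrame(truth_rows)
    return SimulatedAnnotation(gtf_text, fasta_text, truth, transcripts, exons)


class SimulatedDE(NamedTuple):
    tx_de: pd.DataFrame
    gene_de: pd.DataFrame
    truth: pd.DataFrame  # planted switch transcripts


def simulate_de_tables(annotation_truth: pd.DataFrame, config: SimulationConfig) -> SimulatedDE:
    """Simulate transcript- and gene-level DE tables with planted switches.

    Switch genes are drawn from genes with a protein-coding isoform where
    available; the planted isoform gets log2FC >= ``switch_effect`` (positive,
    so planted transcripts occupy the top ranks) and q < 0.01, while the gene
    row stays null.  Every other row is null: log2FC ~ N(0, 0.2), q uniform
    on (0.05, 1].
    """
    if config.n_switch_genes > config.n_genes:
        raise ValueError(
            f"n_switch_genes={config.n_switch_genes} exceeds n_genes={config.n_genes}"
        )
    rng = np.random.default_rng(config.seed + 1_000_003)
    truth = annotation_truth

    coding_genes = sorted(
        truth.loc[truth["biotype"] == "protein_coding", "gene_name"].unique()
    )
    all_genes = sorted(truth["gene_name"].unique())
    pool = coding_genes if len(coding_genes) >= config.n_switch_genes else all_genes
    switch_genes = sorted(
        rng.choice(pool, size=config.n_switch_genes, replace=False)
    ) if config.n_switch_genes else []

    planted: dict[str, str] = {}  # gene_name -> planted transcript_id
    for gene in switch_genes:
        sub = truth.loc[truth["gene_name"] == gene]
        coding = sub.loc[sub["biotype"] == "protein_coding"]
        pick = (coding if not coding.empty else sub).iloc[0]
        planted[gene] = pick["transcript_id"]

    tx_rows = []
    planted_rows = []
    for row in truth.itertuples():
        if planted.get(row.gene_name) == row.transcript_id:
            log2fc = config.switch_effect + float(rng.uniform(0.0, 0.5))
            qvalue = float(rng.uniform(1e-4, 0.009))
            planted_rows.append(
                {
                    "transcript_id": row.transcript_id,
                    "gene_id": row.gene_id,
                    "gene_name": row.gene_name,
                    "biotype": row.biotype,
                    "log2fc": log2fc,
                    "qvalue": qvalue,
                }
            )
        else:
            log2fc = float(rng.normal(0.0, 0.2))
            qvalue = float(rng.uniform(0.051, 1.0))
        pvalue = qvalue * float(rng.uniform(0.1, 1.0))
        tx_rows.append(
            {
                "transcript_id": row.transcript_id,
                "log2fc": log2fc,
                "pvalue": pvalue,
                "qvalue": qvalue,
            }
        )

    gene_rows = []
    for gene_id, gene_name in (
        truth[["gene_id", "gene_name"]].drop_duplicates().itertuples(index=False)
    ):
        if gene_name in planted:
            log2fc = float(rng.normal(0.0, 0.05))
            qvalue = float(rng.uniform(0.51, 1.0))
        else:
            log2fc = float(rng.normal(0.0, 0.2))
            qvalue = float(rng.uniform(0.051, 1.0))
        pvalue = qvalue * float(rng.uniform(0.1, 1.0))
        gene_rows.append(
            {"gene_id": gene_id, "log2fc": log2fc, "pvalue": pvalue, "qvalue": qvalue}
        )

    return SimulatedDE(
        tx_de=pd.DataFrame(tx_rows),
        gene_de=pd.DataFrame(gene_rows),
        truth=pd.DataFrame(
            planted_rows,
            columns=["transcript_id", "gene_id", "gene_name", "biotype", "log2fc", "qvalue"],
        ),
    )


class SimulatedTPM(NamedTuple):
    matrix: pd.DataFrame  # transcripts x samples
    sample_groups: dict[str, str]
    truth: pd.DataFrame  # per-transcript planted group means


def simulate_tpm(
    annotation_truth: pd.DataFrame,
    config: SimulationConfig,
    de_truth: pd.DataFrame | None = None,
) -> SimulatedTPM:
    """Simulate a log-normal TPM matrix consistent with the planted switches.

    Control-group means are log-normal across transcripts; planted switch
    isoforms get their case-group mean multiplied by ``2**log2fc`` (taken from
    the DE truth when given, else the configured effect), i.e. a linear-space
    separation of at least the effect size.  Column names carry group labels.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    tx_ids = list(annotation_truth["transcript_id"])
    planted_fc = {}
    if de_truth is not None:
        planted_fc = dict(zip(de_truth["transcript_id"], de_truth["log2fc"]))

    n = config.samples_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [f"case_{i + 1}" for i in range(n)]
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}

    base_log2 = rng.normal(4.0, 1.5, size=len(tx_ids))
    noise_sd = 0.25  # log2-scale within-group noise
    data = np.empty((len(tx_ids), 2 * n))
    truth_rows = []
    for i, tx in enumerate(tx_ids):
        fc = float(planted_fc.get(tx, 0.0))
        ctrl_mu, case_mu = base_log2[i], base_log2[i] + fc
        data[i, :n] = 2.0 ** (ctrl_mu + rng.normal(0, noise_sd, size=n))
        data[i, n:] = 2.0 ** (case_mu + rng.normal(0, noise_sd, size=n))
        truth_rows.append(
            {
                "transcript_id": tx,
                "control_log2_mean": ctrl_mu,
                "case_log2_mean": case_mu,
                "noise_sd_log2": noise_sd,
            }
        )
    matrix = pd.DataFrame(data, index=pd.Index(tx_ids, name="transcript_id"), columns=samples)
    return SimulatedTPM(matrix, groups, pd.DataFrame(truth_rows))


class SimulatedGMT(NamedTuple):
    gmt_text: str
    truth: pd.DataFrame  # set name -> member gene, is_planted


def simulate_gmt(
    annotation_truth: pd.DataFrame,
    config: SimulationConfig,
    de_truth: pd.DataFrame | None = None,
) -> SimulatedGMT:
    """Simulate a gene-level GMT database with one planted set.

    The planted set is composed of the switch genes (padded with random genes
    when ``planted_set_fraction`` < 1); the remaining sets draw 10–50 genes
    uniformly.  Because the switch isoforms top the fold-change ranking, the
    planted set is the positive control for stratified enrichment.
    """
    rng = np.random.default_rng(config.seed + 3_000_003)
    genes = sorted(annotation_truth["gene_name"].unique())
    switch_genes = (
        sorted(de_truth["gene_name"].unique()) if de_truth is not None else []
    )

    sets: dict[str, list[str]] = {}
    truth_rows = []
    if switch_genes:
        members = list(switch_genes)
        if config.planted_set_fraction < 1.0:
            target = int(round(len(switch_genes) / config.planted_set_fraction))
            others = [g for g in genes if g not in set(switch_genes)]
            pad = min(target - len(members), len(others))
            if pad > 0:
                members += sorted(rng.choice(others, size=pad, replace=False))
        sets[PLANTED_SET_NAME] = sorted(members)
        for g in sets[PLANTED_SET_NAME]:
            truth_rows.append({"set_name": PLANTED_SET_NAME, "gene_name": g, "is_planted": True})
    for i in range(config.n_gene_sets - (1 if switch_genes else 0)):
        name = f"RANDOM_SET_{i + 1:03d}"
        size = int(rng.integers(10, min(51, len(genes) + 1)))
        members = sorted(rng.choice(genes, size=size, replace=False))
        sets[name] = members
        for g in members:
            truth_rows.append({"set_name": name, "gene_name": g, "is_planted": False})

    lines = [
        "\t".join([name, "synthetic gene set", *members])
        for name, members in sets.items()
    ]
    gmt_text = "\n".join(lines) + ("\n" if lines else "")
    return SimulatedGMT(gmt_text, pd.DataFrame(truth_rows))


def _de_to_tsv(frame: pd.DataFrame) -> str:
    return frame.to_csv(sep="\t", index=False, float_format="%.10g")


def write_fixture_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a complete fixture directory; byte-deterministic per seed.

    Writes ``reference.gtf``, ``transcripts.fa``, ``tx_de.tsv``,
    ``gene_de.tsv``, ``tpm.tsv``, ``sample_groups.tsv``, ``sets.gmt`` and the
    truth tables, and returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(config)
    de = simulate_de_tables(ann.truth, config)
    tpm = simulate_tpm(ann.truth, config, de.truth)
    gmt = simulate_gmt(ann.truth, config, de.truth)

    paths = {
        "gtf": out_dir / "reference.gtf",
        "fasta": out_dir / "transcripts.fa",
        "tx_de": out_dir / "tx_de.tsv",
        "gene_de": out_dir / "gene_de.tsv",
        "tpm": out_dir / "tpm.tsv",
        "groups": out_dir / "sample_groups.tsv",
        "gmt": out_dir / "sets.gmt",
        "annotation_truth": out_dir / "truth_annotation.tsv",
        "switch_truth": out_dir / "truth_switches.tsv",
        "gmt_truth": out_dir / "truth_gmt.tsv",
    }
    paths["gtf"].write_text(ann.gtf_text)
    paths["fasta"].write_text(ann.fasta_text)
    paths["tx_de"].write_text(_de_to_tsv(de.tx_de))
    paths["gene_de"].write_text(_de_to_tsv(de.gene_de))
    tpm_out = tpm.matrix.reset_index()
    paths["tpm"].write_text(tpm_out.to_csv(sep="\t", index=False, float_format="%.10g"))
    groups_frame = pd.DataFrame(
        {"sample": list(tpm.sample_groups), "group": list(tpm.sample_groups.values())}
    )
    paths["groups"].write_text(groups_frame.to_csv(sep="\t", index=False))
    paths["gmt"].write_text(gmt.gmt_text)
    paths["annotation_truth"].write_text(ann.truth.to_csv(sep="\t", index=False))
    paths["switch_truth"].write_text(_de_to_tsv(de.truth))
    paths["gmt_truth"].write_text(gmt.truth.to_csv(sep="\t", index=False))
    return paths
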