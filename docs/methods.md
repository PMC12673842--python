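# Methods

This note records the models, rules, and numerical choices behind
`isoscope`, and what the synthetic fixtures do and do not establish about
real data.

## Annotation dictionary

The dictionary maps every transcript to its parent gene, display names,
length, and biotype. Sources are GENCODE transcript-FASTA headers
(pipe-delimited, eight fields; the HAVANA accession fields are discarded)
and GTF/GFF3 feature lines (both attribute dialects accepted per line).
Conventions:

- **Coordinates** are stored exactly as GTF gives them — 1-based, inclusive
  at both ends; GFF3 input is normalized to the same convention. One
  internal convention, documented once.
- **Accession versions** (`ENST….N`) are preserved in storage; every join in
  the package goes through a version-stripped secondary index, because DE
  tools variably strip versions. A transcript id mapping to two distinct
  (version-stripped) gene ids is a hard error.
- **Source precedence**: when FASTA and GTF disagree on a transcript's
  biotype, the record passed later to `make_tx_to_gene` wins and a warning
  is logged; callers pass FASTA first and GTF second, so GTF metadata — the
  richer source — prevails. A known length is never erased by a later
  record lacking one.
- **Lengths** from FASTA headers are taken verbatim; transcripts parsed from
  GTF without a length attribute get the sum of their exon lengths. Missing
  exon numbers are assigned 5′→3′ along the strand.
- **Biotype normalization**: raw GENCODE tokens are mapped onto a small set
  of analysis categories through an editable table
  (`biotypes.DEFAULT_BIOTYPE_MAP`, overridable from YAML). In particular
  `processed_transcript` and `protein_coding_CDS_not_defined` — the same
  biological object under different release vocabularies — both map to the
  category `CDS_undefined`. Unknown tokens fall to `other` rather than
  erroring, so vocabulary drift never halts an analysis.
- `fetch_reference` is best-effort plumbing: the GENCODE archive URL is a
  pure function of (species, release, artifact), a warm cache short-circuits
  the network, and nothing else in the package depends on it.

## Significance rules

A transcript is called differentially expressed when

    |log2FC| >= t_cat   and   q < 0.05

with `t_cat = 1.0` for the coding-locus categories (protein_coding,
retained_intron, nonsense_mediated_decay, CDS_undefined) and `t_cat = 0.5`
for lncRNA, whose lower expression makes the stricter cut discard real
signal. Boundary semantics are deliberate and tested: the fold-change bound
is inclusive, the q-value bound strict, and the lncRNA rule is applied to
the *absolute* fold change — treating down-regulated lncRNAs asymmetrically
would be indefensible. Categories without an explicit rule (including
`unannotated`) use the coding-locus default; everything is overridable via
`ThresholdPolicy`. Rows with missing q-values are flagged not significant
and counted in a warning rather than dropped.

Gene-level tables are always flagged with the coding-locus rule. Whether
lncRNA *genes* should get the relaxed cut is genuinely open; applying one
uniform gene rule keeps the switch definition simple, and the policy object
makes the alternative a one-liner.

## Isoform-switch candidates (DET without DEG)

The candidate table contains exactly the significant transcripts whose
parent gene is not significant at gene level. Genes absent from the gene
table are treated as "not DE" for inclusion but flagged `untested` in the
tri-state `gene_is_significant` column, so users can filter them out; this
inclusive-with-flag rule was a design choice — silently dropping such
transcripts would hide candidates merely because the gene-level tool
filtered the gene. When a `contrast` column is present in both tables all
operations group by it; absence means a single comparison.

Terminus-collapsed clusters (near-identical isoforms with statistically
indistinguishable read assignments) are removed from the transcript table
before interpretation, by version-insensitive id match; membership entries
naming absent transcripts are ignored with a warning.

## Stratified preranked enrichment

No transcript-level pathway databases exist, so gene-level GMT sets are
*projected*: each set's genes are replaced by all of their transcripts whose
category matches the stratum. Strata are the four single categories plus
`lncRNA` and `non_coding_group`, the pool of the three
alternative-processing categories (retained_intron, nonsense_mediated_decay,
CDS_undefined) — coding enrichment versus its non-coding opposition. Sets
with fewer than `min_size` (default 5) surviving transcripts are dropped.
The projection assumes a transcript inherits its gene's annotation, which
is exactly the assumption being probed when coding and non-coding strata
disagree.

**Ranking.** The stratum's *entire tested* transcript table is ranked by
log2FC descending — a preranked walk needs the full background, not only
the significant calls. Ties are broken by ascending q-value, then
transcript id, so the order is fully deterministic. log2FC was chosen over
a signed −log10 p statistic because the package's displays are
fold-change-centric; the ranking column is a parameter.

**Statistic.** The running sum walks the ranked list: hit increments
|s_i|^p / Σ_hits |s_j|^p, miss decrements 1/(N − N_h); ES is the signed
value of maximal absolute deviation (first occurrence wins exact ties). The
default weight exponent is p = 1, the conventional weighted choice; p = 0
gives the unweighted walk, for which the ES of a set and of its complement
are exact mirror images. Degenerate inputs error out: an empty intersection
with the ranked list, or a set covering it (the miss decrement is then
undefined). If every hit statistic is exactly zero under p > 0, the walk
falls back to equal increments rather than dividing by zero.

**Null and p-value.** `n_perm` (default 1000) member sets of the same size
are drawn uniformly without replacement from the ranked list. The p-value
is sign-matched and +1-smoothed,

    p = (1 + #{null: same sign, |ES_null| >= |ES|}) / (1 + #{null: same sign}),

which cannot be zero at finite `n_perm`; NES divides ES by the mean |ES|
of the matching-sign null, and is reported as missing (NaN) when that null
is empty (the p-value then falls back to the smoothed 1.0). Permutations are
vectorized and chunked (≤4M matrix elements at a time) so memory stays flat.
Benjamini–Hochberg adjustment is applied *within* each stratum — the strata
answer different questions, and pooling them would let a large stratum
dilute a small one. Determinism: one generator per stratum, seeded from
(seed, stratum index), with sets scored in sorted-name order.

Verified properties (in the test suite and `scripts/acceptance.py`): exact
equality of the vectorized walk with a naive brute-force oracle on random
instances; Monte-Carlo p-values within 0.01 of the exhaustive
15-combination null at N=6, set size 2; and empirical type-I error at
α = 0.05 inside [0.03, 0.07] over 2000 random sets on a null ranked list
(the +1 smoothing makes it mildly conservative, ≈0.045 at 200
permutations).

## Plot models

Plots are built as declarative mark lists (bars, lines, whiskers,
rectangles, segments, labels) in data units; the renderer is a thin,
deterministic matplotlib pass that recomputes nothing. Models, not pixels,
are the test surface.

- *Fold-change profile*: one bar per isoform plus one for the gene, colored
  by category; non-significant bars at opacity 0.3, significant at 1.0;
  faceted per contrast. A gene never tested at gene level is drawn at 0
  under a distinct `gene_untested` key rather than omitted.
- *Expression profile*: per (isoform, group), mean TPM and the sample
  standard deviation (ddof = 1; a single-sample group gets SD 0 and a
  degenerate whisker). The dispersion indicator is modeled as a symmetric
  whisker spanning mean ± 1 SD. Group order follows the sample→group map.
- *Genomic context*: one row per transcript ordered by genomic start
  (ascending, ties by id), so plus-strand models read left→right and
  minus-strand models' 5′ ends sit at the right; exons are rectangles,
  introns plain segments across the exact inter-exon gap (no chevrons —
  strand is conveyed by the label and the ordering rule). Input must be a
  single chromosome.

SVG/PDF output pins the hash salt and strips timestamps, so identical
models render to identical bytes.

## Synthetic fixtures

The simulator emulates the *structure* of a small two-group bulk RNA-seq
study, not its read-level physics. Defaults: 60 genes on two chromosomes
with alternating strands, 2–4 isoforms each with 1–8 non-overlapping exons
(50–300 nt, introns 50–500 nt), a roughly GENCODE-like biotype mix
(45% protein_coding, 20% lncRNA, 15% retained_intron, 10% NMD, 10%
CDS-not-defined), 20 switch genes with a planted isoform effect of
log2FC ≥ 2, 20 gene sets of 10–50 genes, and 5 samples per group. These
sizes keep every end-to-end check comfortably inside a desktop run while
leaving all planted effects far from the decision boundaries.

Planted switch isoforms get a positive log2FC at or above the effect size
and q < 0.01 while their gene rows stay null (q > 0.5); all other rows draw
log2FC ~ N(0, 0.2) with q uniform on (0.05, 1], which keeps chance
significance off the strict q < 0.05 boundary *by construction* — boundary
behavior is therefore tested separately with hand-written rows, and the
zero-false-positive property of switch recovery is a property of these
study conditions, not of arbitrary data. TPMs are log-normal (log2 means
~N(4, 1.5), within-group noise SD 0.25 in log2) with planted isoforms
separated by 2^log2FC in the case group. The planted GMT set is composed of
the switch genes, whose isoforms therefore occupy the top ranks — the
positive control for stratified enrichment. Truth tables are first-class
outputs, so tests never re-derive the planted signal from the data.

What the fixtures do **not** model: quantification uncertainty (no Gibbs
resamples), expression covariance between isoforms of a gene, realistic
library-size effects, overlapping genes, or annotation errors. Passing
tests demonstrate the correctness of the bookkeeping and the statistics
under clean planted signal — not the sensitivity of the workflow on noisy
real quantifications.

## Known limitations

- Only GENCODE-style FASTA headers are parsed (Ensembl/RefSeq header
  dialects are out of scope), and no sequence-level operations (ORF calling,
  k-mer work) are performed.
- Enrichment uses a plain Monte-Carlo permutation null; very small p-values
  saturate at 1/(1 + n_perm) rather than being refined adaptively.
- The gene-set projection inherits every limitation of gene-level
  annotation; a set enriched in the NMD stratum means "genes of this
  pathway produce NMD-flagged isoforms here", not that the isoforms have a
  demonstrated function.
- `fetch_reference` performs no checksum verification of downloads.
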