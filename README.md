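# isoscope

Transcript-level interpretation of RNA-seq differential-expression results.

Most RNA-seq studies are analyzed at the gene level, collapsing all isoforms
of a locus into one expression value and discarding the biology of
alternative splicing and alternative transcription start/end sites. When
differential expression *is* computed per transcript, the hard part moves
downstream: hundreds of differentially expressed transcripts (DETs) need to
be tied back to genes, transcript biotypes, and pathways before they mean
anything. `isoscope` is a toolkit for exactly that downstream step. It does
**not** quantify reads or fit DE models — it consumes transcript- and
gene-level DE tables (from swish, edgeR, or any tool producing
`feature_id, log2FC, p, q`) together with a GENCODE-style reference, and
produces:

- a **transcript↔gene dictionary** parsed from GENCODE FASTA headers and/or
  GTF/GFF3, with a version-insensitive accession index and normalized
  transcript-biotype categories;
- **biotype-aware significance calls**: a transcript is differentially
  expressed when |log2FC| ≥ 1 and q < 0.05 for mRNA-class isoforms
  (protein_coding, retained_intron, nonsense-mediated decay, CDS-undefined),
  or |log2FC| ≥ 0.5 and q < 0.05 for lncRNA isoforms, which are expressed at
  lower levels;
- the **isoform-switch candidate table** (DET-without-DEG): significant
  transcripts whose parent gene shows no gene-level change — the signature
  of switching between isoforms of a locus;
- **transcript-type-stratified gene-set enrichment**: gene-level GMT
  databases are projected onto transcripts and a natively implemented
  preranked GSEA (running-sum ES, permutation null, sign-matched NES,
  Benjamini–Hochberg within stratum) is run separately per biotype category,
  separating what coding isoforms do from what non-coding isoforms of the
  same loci do;
- **declarative plot models** (fold-change bar profiles, group-mean TPM
  profiles with ±SD whiskers, exon/intron genomic-context tracks) rendered
  to png/svg/pdf;
- a **seeded simulator** that generates a complete synthetic study
  (reference, DE tables, TPM matrix, GMT with a planted set) so the whole
  workflow is testable offline.

The enrichment statistic is the classic weighted Kolmogorov–Smirnov-like
running sum: walking the list of transcripts ranked by log2FC, a set member
at rank *i* increments the sum by |s_i|^p / Σ_hits |s_j|^p and a non-member
decrements it by 1/(N − N_h); the enrichment score ES is the signed maximal
deviation, and its p-value comes from random same-size member sets
(+1-smoothed, sign-matched).

## Worked example

Simulate a small two-group study (60 genes, 20 planted isoform-switch
genes), build the dictionary, extract switch candidates, and run stratified
enrichment:

```sh
isoscope simulate --out study --seed 11
isoscope make-dict --fasta study/transcripts.fa --gtf study/reference.gtf --out dict.tsv
isoscope switches  --dict dict.tsv --tx-de study/tx_de.tsv --gene-de study/gene_de.tsv --out switches.tsv
isoscope enrich    --dict dict.tsv --tx-de study/tx_de.tsv --gmt study/sets.gmt \
                   --stratum protein_coding --stratum non_coding_group --seed 3 --out enrichment.tsv
```

which prints

```
wrote 10 fixture file(s) to study
wrote 181 transcripts to dict.tsv
20 isoform-switch candidate(s)
40 enrichment row(s) across 2 stratum/strata
```

The 20 recovered switch candidates are exactly the 20 planted switch
isoforms (`study/truth_switches.tsv`): transcripts with a strong log2FC and
small q whose genes stayed flat. The top of the protein-coding enrichment
stratum:

```
       stratum            pathway  size       es      nes   pvalue     padj
protein_coding PLANTED_SWITCH_SET    26 0.978804 1.625467 0.001001 0.020020
protein_coding     RANDOM_SET_001    22 0.664234 1.101395 0.253253 0.633133
```

`PLANTED_SWITCH_SET` — the set built from the switch genes, whose isoforms
occupy the top ranks — is the only set with padj < 0.05, as it should be;
the random sets hover near their null expectation.

Gene-level plots come from `plot-profile` (per-isoform log2FC bars, colored
by biotype, non-significant bars translucent), `plot-expression` (group-mean
TPM lines with ±1 SD whiskers per isoform), and `plot-context` (exon
rectangles and intron lines, transcript rows ordered by genomic start).
Every command also works on real tables: point `--tx-de`/`--gene-de` at your
DE output, `--fasta`/`--gtf` at a GENCODE release, and `--gmt` at any
gene-level database (GO, REACTOME, MSigDB).

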