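"""Transcript-type-stratified preranked gene-set enrichment.

Gene-level GMT databases are projected onto transcripts: every gene's set
membership is inherited by its transcripts, and enrichment runs separately
per transcript category (protein_coding, retained_intron,
nonsense_mediated_decay, CDS_undefined, lncRNA, or the pooled
``non_coding_group`` of the three alternative-processing categories).  This
separates what coding isoforms do from what non-coding isoforms of the same
loci do — which a gene-level enrichment cannot distinguish.

The enrichment statistic is the classic preranked running sum: walk the
ranked transcript list; on a set member ("hit") increment by
``|stat|^p / sum_hits |stat|^p``, on a miss decrement by ``1/(N - Nh)``.
The enrichment score (ES) is the signed value of maximal absolute deviation
from zero.  Significance comes from a permutation null of random same-size
member sets, with a sign-matched +1-smoothed p-value and a sign-matched
normalized ES (NES); Benjamini–Hochberg adjustment is applied within each
stratum, because the strata answer different questions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation import TxToGeneTable, strip_version
from .biotypes import stratum_categories
from .errors import EnrichmentError, ParseError

log = logging.getLogger(__name__)

#: Column order of the enrichment result TSV.
RESULT_COLUMNS = ["stratum", "pathway", "size", "es", "nes", "pvalue", "padj", "leading_edge"]

# cap on elements of any one permutation scoring matrix (memory control)
_CHUNK_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class GeneSet:
    """One named gene set (GMT line): name, description, member symbols/ids."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class TranscriptSetCollection:
    """Gene sets projected onto the transcripts of one biotype stratum."""

    stratum: str
    sets: dict[str, frozenset[str]]
    n_unmatched_genes: int = 0


@dataclass(frozen=True)
class RankedList:
    """Transcripts ordered by a ranking statistic, best first.

    Ties are broken deterministically (ascending q-value, then transcript_id)
    before construction, so equal statistics still yield a reproducible walk.
    """

    ids: tuple[str, ...]
    stats: np.ndarray  # float64, same length as ids

    def __post_init__(self):
        if len(self.ids) != len(self.stats):
            raise ValueError("ids and stats must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list contains duplicate transcript ids")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs of one enrichment run.

    min_size:
        Smallest surviving transcript set scored (default 5; small sets give
        unstable running sums).
    weight_exponent:
        ``p`` of the hit increment ``|stat|^p`` (default 1, the conventional
        weighted statistic; 0 gives the unweighted Kolmogorov–Smirnov-like
        walk).
    n_perm:
        Permutations of the null (default 1000).
    seed:
        Mandatory; fixes every random draw.
    """

    min_size: int = 5
    weight_exponent: float = 1.0
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def read_gmt(source: str | Path | IO[str] | Iterable[str]) -> dict[str, GeneSet]:
    """Parse a GMT stream: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are deduplicated and empty member tokens
    dropped.  Lines with fewer than three fields and duplicate set names are
    errors (with line numbers).
    """
    from .annotation import _as_lines  # shared line-source handling

    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line has {len(fields)} tab-separated fields, expected >= 3",
                line_number=lineno,
            )
        name, description = fields[0], fields[1]
        if name in sets:
            raise ParseError(f"duplicate gene-set name {name!r}", line_number=lineno)
        members = frozenset(tok for tok in fields[2:] if tok)
        if not members:
            raise ParseError(f"gene set {name!r} has no non-empty members", line_number=lineno)
        sets[name] = GeneSet(name=name, description=description, members=members)
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path: str | Path | IO[str] | None = None) -> str:
    """Serialize gene sets to GMT text (members sorted for determinism)."""
    lines = [
        "\t".join([s.name, s.description, *sorted(s.members)]) for s in sets.values()
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        if hasattr(path, "write"):
            path.write(text)
        else:
            Path(path).write_text(text)
    return text


def expand_gene_sets(
    collection: Mapping[str, GeneSet],
    tx_to_gene: TxToGeneTable,
    stratum: str,
    min_size: int = 5,
    biotype_map: dict[str, str] | None = None,
) -> TranscriptSetCollection:
    """Project gene-level sets onto the transcripts of one biotype stratum.

    Each set's gene members (symbols or gene_ids, version-insensitive) are
    replaced by all transcripts of those genes whose category matches the
    stratum; ``non_coding_group`` pools the three alternative-processing
    categories.  Sets with fewer than ``min_size`` surviving transcripts are
    dropped (logged).  Gene symbols matching nothing in the dictionary are
    skipped per set but counted globally.
    """
    from .biotypes import biotype_category

    cats = set(stratum_categories(stratum))
    frame = tx_to_gene.frame
    in_stratum = frame["transcript_type"].map(
        lambda b: biotype_category(b, biotype_map) in cats
    )
    sub = frame.loc[in_stratum]
    gene_to_tx: dict[str, set[str]] = {}
    for row in sub.itertuples():
        txs_name = gene_to_tx.setdefault(str(row.gene_name), set())
        txs_name.add(row.transcript_id)
        gkey = strip_version(str(row.gene_id))
        if gkey != str(row.gene_name):
            gene_to_tx.setdefault(gkey, set()).add(row.transcript_id)

    known_genes = set(frame["gene_name"].astype(str)) | {
        strip_version(str(g)) for g in frame["gene_id"]
    }

    out: dict[str, frozenset[str]] = {}
    n_unmatched = 0
    n_dropped = 0
    for name in sorted(collection):
        gset = collection[name]
        txs: set[str] = set()
        for member in gset.members:
            key = strip_version(str(member))
            if key not in known_genes:
                n_unmatched += 1
                continue
            txs |= gene_to_tx.get(key, set())
        if len(txs) < min_size:
            n_dropped += 1
            continue
        out[name] = frozenset(txs)
    if n_dropped:
        log.info(
            "stratum %s: dropped %d set(s) below min_size=%d", stratum, n_dropped, min_size
        )
    if n_unmatched:
        log.info(
            "stratum %s: %d gene member token(s) matched nothing in the dictionary",
            stratum,
            n_unmatched,
        )
    return TranscriptSetCollection(stratum=stratum, sets=out, n_unmatched_genes=n_unmatched)


def rank_transcripts(
    annotated_rows: pd.DataFrame, stratum: str, stat_col: str = "log2fc"
) -> RankedList:
    """Rank a stratum's tested transcripts by log2 fold-change, best first.

    All tested transcripts of the stratum enter the list — a preranked walk
    needs the full background, not only the significant calls.  Ties on the
    statistic are broken by ascending q-value, then transcript_id, making the
    order fully deterministic.  An empty stratum yields an empty list.
    """
    cats = set(stratum_categories(stratum))
    rows = annotated_rows.loc[annotated_rows["category"].isin(cats)].copy()
    if rows.empty:
        log.warning("stratum %s has no tested transcripts", stratum)
        return RankedList(ids=(), stats=np.empty(0))
    rows["_stat"] = pd.to_numeric(rows[stat_col], errors="coerce")
    rows["_q"] = pd.to_numeric(rows.get("qvalue"), errors="coerce").fillna(np.inf)
    rows = rows.dropna(subset=["_stat"])
    rows = rows.sort_values(
        by=["_stat", "_q", "transcript_id"], ascending=[False, True, True], kind="mergesort"
    )
    return RankedList(
        ids=tuple(rows["transcript_id"]), stats=rows["_stat"].to_numpy(float)
    )


def _hit_weights(stats: np.ndarray, hit: np.ndarray, p: float) -> np.ndarray:
    """Per-position hit increments |stat|^p normalized to sum 1 over hits.

    Degenerate case: if every hit statistic is zero (total weight 0) the walk
    falls back to equal increments, as if p were 0.
    """
    if p == 0:
        w = np.ones(len(stats))
    else:
        w = np.abs(stats) ** p
    total = float(np.sum(w[hit]))
    if total == 0.0:
        w = np.ones(len(stats))
        total = float(np.sum(w[hit]))
    return w / total


def enrichment_score(
    ranked: RankedList,
    member_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Walk the ranked list and return (ES, running-sum profile).

    ES is the running-sum value of maximal absolute deviation from zero
    (signed; first occurrence wins on exact ties).  The profile has one value
    per ranked position, after processing that position.

    Raises
    ------
    EnrichmentError
        If the member set misses the ranked list entirely, or covers it
        (the miss decrement ``1/(N - Nh)`` is then undefined).
    """
    members = set(member_set)
    hit = np.fromiter((t in members for t in ranked.ids), bool, count=len(ranked))
    return _score_from_mask(ranked.stats, hit, weight_exponent)


def _score_from_mask(
    stats: np.ndarray, hit: np.ndarray, p: float
) -> tuple[float, np.ndarray]:
    n = len(stats)
    nh = int(hit.sum())
    if nh == 0:
        raise EnrichmentError("member set has empty intersection with the ranked list")
    if nh == n:
        raise EnrichmentError("member set covers the entire ranked list")
    w = _hit_weights(stats, hit, p)
    steps = np.where(hit, w, -1.0 / (n - nh))
    profile = np.cumsum(steps)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


def _leading_edge(
    ranked: RankedList, member_set: set[str], es: float, profile: np.ndarray
) -> tuple[str, ...]:
    """Hits up to (positive ES) or from (negative ES) the running-sum extremum."""
    peak = int(np.argmax(np.abs(profile)))
    if es >= 0:
        span = range(0, peak + 1)
    else:
        span = range(peak, len(ranked))
    return tuple(t for i in span if (t := ranked.ids[i]) in member_set)


def _null_scores(
    stats: np.ndarray, nh: int, p: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random size-``nh`` sets drawn without replacement."""
    n = len(stats)
    if p == 0:
        wabs = np.ones(n)
    else:
        wabs = np.abs(stats) ** p
    out = np.empty(n_perm)
    chunk = max(1, _CHUNK_ELEMENTS // n)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random size-nh subsets: indices of the nh smallest uniforms per row
        r = rng.random((m, n))
        idx = np.argpartition(r, nh - 1, axis=1)[:, :nh]
        hits = np.zeros((m, n), dtype=bool)
        hits[np.arange(m)[:, None], idx] = True
        totals = (wabs * hits).sum(axis=1)
        zero = totals == 0.0
        inc = np.where(hits, wabs, 0.0)
        if zero.any():
            inc[zero] = hits[zero].astype(float)
            totals[zero] = nh
        steps = inc / totals[:, None] - (~hits) / (n - nh)
        prof = np.cumsum(steps, axis=1)
        out[done : done + m] = prof[np.arange(m), np.argmax(np.abs(prof), axis=1)]
        done += m
    return out


@dataclass(frozen=True)
class PermutationResult:
    es: float
    nes: float  # NaN when the matching-sign null is empty
    pvalue: float
    n_perm: int


def permutation_pvalue(
    ranked: RankedList,
    member_set: Iterable[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Permutation significance of a set's ES against random same-size sets.

    The null draws ``n_perm`` member sets of the same size uniformly without
    replacement from the ranked list.  The p-value is sign-matched and
    +1-smoothed::

        p = (1 + #{null: sign matches and |null| >= |es|}) / (1 + #{null: sign matches})

    and ``nes = es / mean(|null es| of matching sign)``.  When no null draw
    matches the observed sign, NES is reported as NaN and the p-value falls
    back to the smoothed value 1/(1+0) = 1.  Fully reproducible given a seed.
    """
    members = set(member_set)
    hit = np.fromiter((t in members for t in ranked.ids), bool, count=len(ranked))
    es, _ = _score_from_mask(ranked.stats, hit, weight_exponent)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = _null_scores(ranked.stats, int(hit.sum()), weight_exponent, n_perm, rng)
    return PermutationResult(
        es=es, n_perm=n_perm, **_pvalue_from_null(es, null)
    )


def _pvalue_from_null(es: float, null: np.ndarray) -> dict[str, float]:
    if es == 0.0:
        return {"pvalue": 1.0, "nes": float("nan")}
    matching = null > 0 if es > 0 else null < 0
    n_match = int(matching.sum())
    n_extreme = int((matching & (np.abs(null) >= abs(es))).sum())
    pvalue = (1 + n_extreme) / (1 + n_match)
    if n_match == 0:
        log.warning("no matching-sign null permutation; NES undefined")
        nes = float("nan")
    else:
        nes = es / float(np.mean(np.abs(null[matching])))
    return {"pvalue": pvalue, "nes": nes}


def run_enrichment(
    annotated_rows: pd.DataFrame,
    gmt_collection: Mapping[str, GeneSet],
    tx_to_gene: TxToGeneTable,
    strata: Sequence[str],
    params: EnrichmentParams,
    biotype_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Stratified preranked enrichment over every requested transcript stratum.

    For each stratum: expand the gene sets to transcripts, rank the stratum's
    tested transcripts, score every surviving set, compute permutation
    p-values, and Benjamini–Hochberg-adjust within the stratum.  The
    concatenated table is sorted by (stratum, padj).  Strata with an empty
    ranked list contribute zero rows (warned).
    """
    if not strata:
        raise ValueError("strata must be non-empty")
    frames: list[pd.DataFrame] = []
    for si, stratum in enumerate(strata):
        ranked = rank_transcripts(annotated_rows, stratum)
        if len(ranked) == 0:
            continue
        expanded = expand_gene_sets(
            gmt_collection, tx_to_gene, stratum, params.min_size, biotype_map
        )
        present = set(ranked.ids)
        rng = np.random.default_rng([params.seed, si])
        rows = []
        for name in sorted(expanded.sets):
            members = expanded.sets[name] & present
            if not (0 < len(members) < len(ranked)):
                continue
            res = permutation_pvalue(
                ranked, members, params.weight_exponent, params.n_perm, rng
            )
            _, profile = enrichment_score(ranked, members, params.weight_exponent)
            ledge = _leading_edge(ranked, set(members), res.es, profile)
            rows.append(
                {
                    "stratum": stratum,
                    "pathway": name,
                    "size": len(members),
                    "es": res.es,
                    "nes": res.nes,
                    "pvalue": res.pvalue,
                    "leading_edge": ",".join(ledge),
                }
            )
        if not rows:
            continue
        frame = pd.DataFrame(rows)
        frame["padj"] = multipletests(frame["pvalue"], method="fdr_bh")[1]
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["stratum", "padj", "pathway"], kind="mergesort").reset_index(
        drop=True
    )
    return out[RESULT_COLUMNS]
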