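"""GENCODE-style reference parsing and the transcript-to-gene dictionary.

Builds the central annotation dictionary ("tx2gene") from GENCODE transcript
FASTA headers and/or GTF/GFF3 feature lines, plus exon tables for genomic
context plots.  Coordinates are stored exactly as GTF gives them: 1-based,
inclusive at both ends; GFF3 input is normalized to the same convention.
Accession versions (the trailing ``.N``) are preserved in storage, and all
joins elsewhere in the package go through a version-stripped secondary index,
because differential-expression tools variably strip versions.
"""

from __future__ import annotations

import io
import logging
import re
import urllib.request
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

from .errors import AnnotationError, ParseError

log = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")

#: Column order of the TSV dictionary export.
DICT_COLUMNS = [
    "transcript_id",
    "gene_id",
    "transcript_name",
    "gene_name",
    "length",
    "transcript_type",
]


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix from an accession string."""
    return _VERSION_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript's identity, parent gene, biotype, and length (nt)."""

    transcript_id: str
    gene_id: str
    transcript_name: str
    gene_name: str
    length: int | None
    biotype: str

    def __post_init__(self):
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.biotype:
            raise ValueError(f"{self.transcript_id}: biotype must be non-empty")
        if self.length is not None and self.length < 1:
            raise ValueError(f"{self.transcript_id}: length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class ExonRecord:
    """One exon's genomic interval (1-based, inclusive) and transcript membership."""

    transcript_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_number: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"{self.transcript_id}: exon start {self.start} > end {self.end}"
            )
        if self.exon_number < 1:
            raise ValueError(f"{self.transcript_id}: exon_number must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _as_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    """Yield lines from a path, an open text handle, a string, or an iterable."""
    if isinstance(source, Path):
        with open(source) as handle:
            yield from handle
        return
    if isinstance(source, str):
        if source and "\n" not in source and Path(source).is_file():
            with open(source) as handle:
                yield from handle
            return
        yield from io.StringIO(source)
        return
    yield from source


def parse_fasta_headers(fasta: str | Path | IO[str] | Iterable[str]) -> list[TranscriptRecord]:
    """Parse GENCODE transcript-FASTA headers into transcript records.

    GENCODE headers are pipe-delimited with at least eight fields::

        >ENST...|ENSG...|OTTHUMG...|OTTHUMT...|name-201|name|1500|protein_coding|

    Fields three and four (HAVANA accessions, often ``-`` placeholders) are
    discarded.  Sequence bodies are skipped entirely; only header lines are
    read.

    Raises
    ------
    ParseError
        If a header has fewer than eight pipe-delimited fields or a
        non-integer length field, naming the offending line.
    """
    records: list[TranscriptRecord] = []
    for lineno, line in enumerate(_as_lines(fasta), start=1):
        line = line.rstrip("\n")
        if not line.startswith(">"):
            continue
        fields = line[1:].split("|")
        # a trailing delimiter yields one empty final token; drop it
        if fields and fields[-1] == "":
            fields = fields[:-1]
        if len(fields) < 8:
            raise ParseError(
                f"FASTA header has {len(fields)} pipe-delimited fields, expected >= 8: {line!r}",
                line_number=lineno,
            )
        try:
            length = int(fields[6])
        except ValueError:
            raise ParseError(
                f"FASTA header length field is not an integer: {fields[6]!r}",
                line_number=lineno,
            ) from None
        records.append(
            TranscriptRecord(
                transcript_id=fields[0],
                gene_id=fields[1],
                transcript_name=fields[4],
                gene_name=fields[5],
                length=length,
                biotype=fields[7],
            )
        )
    return records


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")

#: Attribute keys accepted for the transcript biotype, in precedence order
#: (GTF dialect first, then GFF3 spellings).
_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "biotype")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse a GTF (``key "value";``) or GFF3 (``key=value;``) attribute column."""
    if '"' in attr_field:
        return dict(_GTF_ATTR.findall(attr_field))
    return {k: v.strip() for k, v in _GFF3_ATTR.findall(attr_field)}


def parse_gtf(
    gtf: str | Path | IO[str] | Iterable[str],
    feature_kinds: Sequence[str] = ("transcript", "exon"),
) -> tuple[list[TranscriptRecord], list[ExonRecord]]:
    """Parse GTF/GFF3 feature lines into transcript and exon records.

    Both attribute dialects are accepted on a per-line basis (GTF
    ``key "value";`` and GFF3 ``key=value``); coordinates are 1-based and
    inclusive in both.  Transcript features missing an explicit ``length``
    attribute get the sum of their exon lengths; exon features missing
    ``exon_number`` are numbered 5'→3' along the strand (genomic order for
    ``+``, reversed for ``-``).

    Parameters
    ----------
    feature_kinds:
        Subset of ``{"transcript", "exon"}`` to extract.

    Raises
    ------
    ParseError
        On a requested feature lacking ``transcript_id``, on ``start > end``,
        or on a line with fewer than nine tab-separated columns; the message
        carries the line number.
    """
    unknown = set(feature_kinds) - {"transcript", "exon"}
    if unknown:
        raise ValueError(f"unsupported feature kinds: {sorted(unknown)}")
    want = set(feature_kinds)

    transcripts: list[TranscriptRecord] = []
    # exon rows buffered per transcript so exon_number can be assigned by strand
    raw_exons: list[dict] = []
    for lineno, line in enumerate(_as_lines(gtf), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise ParseError(
                f"expected 9 tab-separated columns, got {len(cols)}", line_number=lineno
            )
        feature = cols[2]
        if feature not in want:
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise ParseError(f"non-integer coordinates {cols[3]!r}..{cols[4]!r}", line_number=lineno) from None
        if start > end:
            raise ParseError(f"start {start} > end {end}", line_number=lineno)
        attrs = _parse_attributes(cols[8])
        if "transcript_id" not in attrs or not attrs["transcript_id"]:
            raise ParseError(
                f"{feature} feature lacks a transcript_id attribute", line_number=lineno
            )
        tx_id = attrs["transcript_id"]
        if feature == "transcript":
            biotype = next((attrs[k] for k in _BIOTYPE_KEYS if k in attrs), "unknown")
            length = int(attrs["length"]) if "length" in attrs else None
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=attrs.get("gene_id", ""),
                    transcript_name=attrs.get("transcript_name", tx_id),
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", "")),
                    length=length,
                    biotype=biotype,
                )
            )
        else:
            raw_exons.append(
                {
                    "transcript_id": tx_id,
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                    "chrom": cols[0],
                    "start": start,
                    "end": end,
                    "strand": cols[6],
                    "exon_number": int(attrs["exon_number"]) if "exon_number" in attrs else None,
                }
            )

    exons = _number_exons(raw_exons)
    if transcripts and exons:
        transcripts = _fill_lengths_from_exons(transcripts, exons)
    return transcripts, exons


def _number_exons(raw_exons: list[dict]) -> list[ExonRecord]:
    """Assign missing exon numbers 5'→3' along the strand, preserving file order."""
    by_tx: dict[str, list[int]] = {}
    for i, row in enumerate(raw_exons):
        by_tx.setdefault(row["transcript_id"], []).append(i)
    for indices in by_tx.values():
        if all(raw_exons[i]["exon_number"] is not None for i in indices):
            continue
        minus = raw_exons[indices[0]]["strand"] == "-"
        ordered = sorted(indices, key=lambda i: raw_exons[i]["start"], reverse=minus)
        for number, i in enumerate(ordered, start=1):
            raw_exons[i]["exon_number"] = number
    return [ExonRecord(**row) for row in raw_exons]


def _fill_lengths_from_exons(
    transcripts: list[TranscriptRecord], exons: list[ExonRecord]
) -> list[TranscriptRecord]:
    sums: dict[str, int] = {}
    for exon in exons:
        sums[exon.transcript_id] = sums.get(exon.transcript_id, 0) + exon.length
    return [
        replace(t, length=sums[t.transcript_id])
        if t.length is None and t.transcript_id in sums
        else t
        for t in transcripts
    ]


class TxToGeneTable:
    """The annotation dictionary: transcripts, parent genes, lengths, biotypes.

    Wraps a :class:`pandas.DataFrame` with columns ``transcript_id, gene_id,
    transcript_name, gene_name, length, transcript_type`` plus a
    version-insensitive lookup index (accessions with the trailing ``.N``
    stripped).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DICT_COLUMNS if c not in frame.columns]
        if missing:
            raise AnnotationError(f"dictionary frame missing columns: {missing}")
        self.frame = frame.loc[:, DICT_COLUMNS].reset_index(drop=True)
        if self.frame["transcript_id"].duplicated().any():
            dups = self.frame.loc[self.frame["transcript_id"].duplicated(), "transcript_id"]
            raise AnnotationError(f"duplicate transcript_id(s): {sorted(set(dups))}")
        self._index: dict[str, int] = {}
        for pos, tx in enumerate(self.frame["transcript_id"]):
            key = strip_version(tx)
            if key in self._index:
                log.warning("version-stripped collision on %s; keeping first occurrence", key)
                continue
            self._index[key] = pos

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, transcript_id: str) -> bool:
        return strip_version(transcript_id) in self._index

    def lookup(self, transcript_id: str) -> pd.Series | None:
        """Version-insensitive lookup; returns the row or ``None``."""
        pos = self._index.get(strip_version(transcript_id))
        return None if pos is None else self.frame.iloc[pos]

    def records(self) -> list[TranscriptRecord]:
        return [
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                transcript_name=row.transcript_name,
                gene_name=row.gene_name,
                length=None if pd.isna(row.length) else int(row.length),
                biotype=row.transcript_type,
            )
            for row in self.frame.itertuples()
        ]

    def to_tsv(self, path: str | Path | IO[str]) -> None:
        out = self.frame.copy()
        out["length"] = out["length"].astype("Int64")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path | IO[str]) -> "TxToGeneTable":
        frame = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={c: "string" for c in DICT_COLUMNS if c != "length"} | {"length": "Int64"},
        )
        for col in DICT_COLUMNS:
            if col != "length":
                frame[col] = frame[col].astype(object)
        return cls(frame)


def make_tx_to_gene(records: Iterable[TranscriptRecord]) -> TxToGeneTable:
    """Build the deduplicated annotation dictionary from parsed records.

    Records may come from :func:`parse_fasta_headers` and/or :func:`parse_gtf`
    concatenated; pass FASTA-derived records first and GTF-derived records
    second, so that when the two sources disagree on a transcript's biotype
    the GTF value wins (a warning is logged).  A missing length in the later
    record never erases a known length.

    Raises
    ------
    AnnotationError
        If one transcript_id maps to two distinct gene_ids, listing the
        offenders.
    """
    merged: dict[str, TranscriptRecord] = {}
    conflicts: list[str] = []
    for rec in records:
        prev = merged.get(rec.transcript_id)
        if prev is None:
            merged[rec.transcript_id] = rec
            continue
        if strip_version(prev.gene_id) != strip_version(rec.gene_id):
            conflicts.append(
                f"{rec.transcript_id}: {prev.gene_id} vs {rec.gene_id}"
            )
            continue
        if rec.biotype != prev.biotype:
            log.warning(
                "biotype conflict for %s: %r -> %r (later source wins)",
                rec.transcript_id,
                prev.biotype,
                rec.biotype,
            )
        merged[rec.transcript_id] = replace(
            rec, length=rec.length if rec.length is not None else prev.length
        )
    if conflicts:
        raise AnnotationError(
            "transcript(s) mapped to more than one gene: " + "; ".join(conflicts)
        )
    frame = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "transcript_name": r.transcript_name,
                "gene_name": r.gene_name,
                "length": r.length,
                "transcript_type": r.biotype,
            }
            for r in merged.values()
        ],
        columns=DICT_COLUMNS,
    )
    return TxToGeneTable(frame)


def prepare_exon_annotation(
    exon_records: Sequence[ExonRecord], gene_names: Sequence[str]
) -> list[ExonRecord]:
    """Select the exons of every transcript of the requested genes.

    Returns exons sorted by (gene_name, transcript_id, genomic start), i.e.
    grouped per transcript, ready for the genomic-context plot model.

    Raises
    ------
    AnnotationError
        If a requested gene name is absent from the annotation.
    """
    if not gene_names:
        raise ValueError("gene_names must be non-empty")
    present = {e.gene_name for e in exon_records}
    missing = [g for g in gene_names if g not in present]
    if missing:
        raise AnnotationError(f"gene(s) not found in exon annotation: {missing}")
    wanted = set(gene_names)
    selected = [e for e in exon_records if e.gene_name in wanted]
    selected.sort(key=lambda e: (e.gene_name, e.transcript_id, e.start))
    return selected


def write_gtf(
    transcripts: Sequence[TranscriptRecord],
    exons: Sequence[ExonRecord],
    source: str = "isoscope",
) -> str:
    """Serialize transcript + exon records back to GTF text.

    Transcript feature spans are derived from each transcript's exons; exon
    lines follow their transcript in the order given.  Used by the simulator
    (so simulated references round-trip byte-identically through
    :func:`parse_gtf`) and for exporting subsets.
    """
    by_tx: dict[str, list[ExonRecord]] = {}
    for exon in exons:
        by_tx.setdefault(exon.transcript_id, []).append(exon)
    lines: list[str] = []
    for tx in transcripts:
        tx_exons = by_tx.get(tx.transcript_id, [])
        if not tx_exons:
            raise AnnotationError(f"{tx.transcript_id}: no exons to serialize")
        chrom = tx_exons[0].chrom
        strand = tx_exons[0].strand
        span = (min(e.start for e in tx_exons), max(e.end for e in tx_exons))
        common = (
            f'transcript_id "{tx.transcript_id}"; gene_id "{tx.gene_id}"; '
            f'gene_name "{tx.gene_name}"; transcript_name "{tx.transcript_name}"; '
            f'transcript_type "{tx.biotype}";'
        )
        lines.append(
            f"{chrom}\t{source}\ttranscript\t{span[0]}\t{span[1]}\t.\t{strand}\t.\t{common}"
        )
        for exon in tx_exons:
            lines.append(
                f"{chrom}\t{source}\texon\t{exon.start}\t{exon.end}\t.\t{strand}\t.\t"
                f"{common} exon_number {exon.exon_number};"
            )
    return "\n".join(lines) + "\n"


# --- GENCODE archive retrieval (best-effort plumbing; nothing else depends on it) ---

_GENCODE_SPECIES_DIR = {"human": "Gencode_human", "mouse": "Gencode_mouse"}
_GENCODE_ARTIFACTS = {
    "gtf": "gencode.v{release}.annotation.gtf.gz",
    "gff3": "gencode.v{release}.annotation.gff3.gz",
    "transcripts_fasta": "gencode.v{release}.transcripts.fa.gz",
}


def reference_url(species: str, release: str, artifact_kind: str) -> str:
    """Deterministic GENCODE archive URL for (species, release, artifact).

    Pure function: no network, no filesystem.  Mouse releases carry their
    ``M`` prefix in ``release`` (e.g. ``"M33"``).
    """
    if species not in _GENCODE_SPECIES_DIR:
        raise ValueError(
            f"unsupported species {species!r}; supported: {sorted(_GENCODE_SPECIES_DIR)}"
        )
    if artifact_kind not in _GENCODE_ARTIFACTS:
        raise ValueError(
            f"unsupported artifact kind {artifact_kind!r}; supported: {sorted(_GENCODE_ARTIFACTS)}"
        )
    filename = _GENCODE_ARTIFACTS[artifact_kind].format(release=release)
    return (
        "https://ftp.ebi.ac.uk/pub/databases/gencode/"
        f"{_GENCODE_SPECIES_DIR[species]}/release_{release}/{filename}"
    )


def fetch_reference(
    species: str, release: str, artifact_kind: str, cache_dir: str | Path
) -> Path:
    """Download a GENCODE reference into ``cache_dir`` unless already cached.

    Returns the cached path without touching the network when the file is
    already present.  Unsupported species/artifact kinds fail before any
    network activity.
    """
    url = reference_url(species, release, artifact_kind)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / url.rsplit("/", 1)[1]
    if target.exists():
        log.info("using cached reference %s", target)
        return target
    try:
        urllib.request.urlretrieve(url, target)  # noqa: S310 - https URL built above
    except Exception as exc:
        if target.exists():
            target.unlink()
        raise IOError(f"failed to download {url}: {exc}") from exc
    return target
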