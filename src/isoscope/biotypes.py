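"""Normalization of GENCODE transcript biotype tokens into analysis categories.

GENCODE's transcript_type vocabulary drifts between releases: the token for a
coding-locus transcript without a defined CDS has been ``processed_transcript``
in older releases and ``protein_coding_CDS_not_defined`` in newer ones.
Downstream significance rules and enrichment strata operate on a small set of
stable *categories*; this module maps raw tokens onto them and ships the map
as editable configuration (a YAML file with ``token: category`` pairs can be
merged over the defaults).

Categories used throughout the package:

``protein_coding``
    Transcripts with an annotated, complete ORF.
``retained_intron``, ``nonsense_mediated_decay``, ``CDS_undefined``
    The three alternative-mRNA-processing products of coding loci; together
    they form the ``non_coding_group`` enrichment stratum.
``lncRNA``
    Long non-coding RNAs, which get a relaxed fold-change threshold because
    they are expressed at lower levels than mRNAs.
``other``
    Anything else (pseudogenes, small RNAs, ...), handled with the default
    significance thresholds.
"""

from __future__ import annotations

from pathlib import Path

import yaml

#: Categories that arise at protein-coding loci and share the mRNA thresholds.
CODING_LOCUS_CATEGORIES = (
    "protein_coding",
    "retained_intron",
    "nonsense_mediated_decay",
    "CDS_undefined",
)

#: The alternative-processing categories pooled into one enrichment stratum.
NON_CODING_GROUP = ("retained_intron", "nonsense_mediated_decay", "CDS_undefined")

#: Strata accepted by the enrichment module.
KNOWN_STRATA = (
    "protein_coding",
    "retained_intron",
    "nonsense_mediated_decay",
    "CDS_undefined",
    "lncRNA",
    "non_coding_group",
)

DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": "protein_coding",
    "retained_intron": "retained_intron",
    "nonsense_mediated_decay": "nonsense_mediated_decay",
    "lncRNA": "lncRNA",
    # CDS-undefined coding-locus products across GENCODE releases
    "protein_coding_CDS_not_defined": "CDS_undefined",
    "processed_transcript": "CDS_undefined",
    "protein_coding_LoF": "CDS_undefined",
}

#: Category assigned to transcripts absent from the annotation dictionary.
UNANNOTATED = "unannotated"


def load_biotype_map(path: str | Path) -> dict[str, str]:
    """Merge a user YAML mapping (``raw_token: category``) over the defaults."""
    with open(path) as handle:
        user = yaml.safe_load(handle) or {}
    if not isinstance(user, dict):
        raise ValueError(f"biotype map {path!s} must be a mapping, got {type(user).__name__}")
    merged = dict(DEFAULT_BIOTYPE_MAP)
    merged.update({str(k): str(v) for k, v in user.items()})
    return merged


def biotype_category(biotype: str, mapping: dict[str, str] | None = None) -> str:
    """Return the analysis category for a raw biotype token.

    Unknown tokens fall through to ``"other"`` so that novel GENCODE
    vocabulary never crashes the pipeline.
    """
    table = DEFAULT_BIOTYPE_MAP if mapping is None else mapping
    return table.get(biotype, "other")


def stratum_categories(stratum: str) -> tuple[str, ...]:
    """Categories whose transcripts belong to an enrichment stratum."""
    if stratum == "non_coding_group":
        return NON_CODING_GROUP
    if stratum not in KNOWN_STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {KNOWN_STRATA}")
    return (stratum,)
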