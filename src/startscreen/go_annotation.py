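"""Join screened CDSs to Gene Ontology terms from UniProt tab exports.

Two files are expected per species: one for reviewed (Swiss-Prot) and one
for unreviewed (TrEMBL) entries, in the UniProt tab-separated export layout
(an ``Entry`` accession column, a gene-names column, and one column per GO
aspect whose cells look like ``term name [GO:0006810]; other [GO:...]``).

Term ranking is by raw frequency — the number of distinct selected CDSs
carrying a term — not by an enrichment statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import StartScreenError
from .selection import ScreenRecord

GO_ID_RE = re.compile(r"GO:\d{7}")
_TERM_RE = re.compile(r"\s*(.*?)\s*\[(GO:\d{7})\]")

ASPECTS = ("P", "F", "C")

_ASPECT_COLUMNS = {
    "biological process": "P",
    "molecular function": "F",
    "cellular component": "C",
}

_ACCESSION_COLUMNS = ("Entry", "entry", "accession", "Accession")
_GENE_COLUMNS = ("Gene Names", "Gene names", "gene", "Gene")


class GoFormatError(StartScreenError):
    """UniProt export is missing a required column."""


@dataclass
class GoAnnotation:
    accession: str
    gene: str
    go_terms: list[tuple[str, str, str]]  # (go_id, aspect, term text)
    reviewed: bool


def _split_go_cell(cell: str, aspect: str) -> list[tuple[str, str, str]]:
    if not isinstance(cell, str) or not cell.strip():
        return []
    terms = []
    for part in cell.split(";"):
        m = _TERM_RE.search(part)
        if m:
            terms.append((m.group(2), aspect, m.group(1)))
    return terms


def parse_uniprot_go(path: str | Path, reviewed: bool) -> Iterator[GoAnnotation]:
    """Stream one GoAnnotation per row of a UniProt tab export."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    acc_col = next((c for c in _ACCESSION_COLUMNS if c in df.columns), None)
    if acc_col is None:
        raise GoFormatError(
            f"{path}: no accession column; expected one of {_ACCESSION_COLUMNS}, "
            f"found {list(df.columns)}"
        )
    gene_col = next((c for c in _GENE_COLUMNS if c in df.columns), None)
    aspect_cols = [
        (col, aspect)
        for col in df.columns
        for key, aspect in _ASPECT_COLUMNS.items()
        if key in col.lower()
    ]
    if not aspect_cols:
        raise GoFormatError(
            f"{path}: no GO aspect column (biological process / molecular "
            f"function / cellular component); found {list(df.columns)}"
        )
    for _, row in df.iterrows():
        accession = (row[acc_col] or "").strip()
        if not accession:
            continue
        gene_cell = row[gene_col] if gene_col else ""
        gene = str(gene_cell).split()[0] if isinstance(gene_cell, str) and gene_cell.strip() else ""
        terms: list[tuple[str, str, str]] = []
        for col, aspect in aspect_cols:
            terms.extend(_split_go_cell(row[col], aspect))
        yield GoAnnotation(accession=accession, gene=gene, go_terms=terms, reviewed=reviewed)


class GoIndex:
    """Annotation lookup by protein accession (exact, then versionless) and
    by gene symbol.  Reviewed entries override unreviewed ones on conflict;
    duplicate rows for one accession merge their term sets."""

    def __init__(self, annotations: Iterable[GoAnnotation] = ()):
        self._by_accession: dict[str, GoAnnotation] = {}
        self._by_gene: dict[str, GoAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: GoAnnotation) -> None:
        for key_map, key in (
            (self._by_accession, ann.accession),
            (self._by_gene, ann.gene),
        ):
            if not key:
                continue
            existing = key_map.get(key)
            if existing is None:
                key_map[key] = GoAnnotation(
                    accession=ann.accession,
                    gene=ann.gene,
                    go_terms=list(dict.fromkeys(ann.go_terms)),
                    reviewed=ann.reviewed,
                )
            else:
                merged = list(dict.fromkeys(existing.go_terms + ann.go_terms))
                existing.go_terms = merged
                existing.reviewed = existing.reviewed or ann.reviewed

    def lookup(self, protein_id: str, gene: str) -> tuple[GoAnnotation | None, str]:
        """Join priority: protein_id exact, versionless protein_id, gene."""
        if protein_id:
            if protein_id in self._by_accession:
                return self._by_accession[protein_id], "protein_id"
            bare = protein_id.split(".")[0]
            if bare in self._by_accession:
                return self._by_accession[bare], "protein_id"
        if gene and gene in self._by_gene:
            return self._by_gene[gene], "gene"
        return None, "UNANNOTATED"


@dataclass
class AnnotatedRecord:
    record: ScreenRecord
    annotation: GoAnnotation | None
    provenance: str  # "protein_id" | "gene" | "UNANNOTATED"


def map_cds_go(records: Iterable[ScreenRecord], index: GoIndex) -> list[AnnotatedRecord]:
    """Join screen records to annotations (protein accession first, then
    gene symbol); unmatched records are flagged UNANNOTATED, never dropped."""
    out = []
    for rec in records:
        ann, prov = index.lookup(rec.protein_id, rec.gene)
        out.append(AnnotatedRecord(record=rec, annotation=ann, provenance=prov))
    return out


def rank_go_terms(
    annotated: Iterable[AnnotatedRecord], aspect: str
) -> list[tuple[str, str, int]]:
    """Rank terms of one aspect by the number of distinct CDSs carrying them.

    Returns (go_id, term text, n_cds) sorted by descending count, ties broken
    lexicographically by GO id.  A CDS with a duplicated term counts once.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"aspect must be one of {ASPECTS}")
    carriers: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for item in annotated:
        if item.annotation is None:
            continue
        for go_id, asp, term in item.annotation.go_terms:
            if asp != aspect:
                continue
            carriers.setdefault(go_id, set()).add(item.record.cds_id)
            names.setdefault(go_id, term)
    ranked = sorted(carriers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(go_id, names[go_id], len(cds)) for go_id, cds in ranked]


def write_ranked_terms_tsv(
    annotated: list[AnnotatedRecord], handle, aspects: tuple[str, ...] = ASPECTS
) -> None:
    handle.write("aspect\tgo_id\tterm\tn_cds\n")
    for aspect in aspects:
        for go_id, term, n in rank_go_terms(annotated, aspect):
            handle.write(f"{aspect}\t{go_id}\t{term}\t{n}\n")
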