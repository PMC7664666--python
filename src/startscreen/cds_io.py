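"""Reading, validating and filtering CDS FASTA files.

Coordinates are 1-based and inclusive throughout: position +1 is the first
nucleotide of the annotated coding sequence (the A of an AUG start codon for
the canonical case).  Sequences are normalized to uppercase RNA (T -> U) on
input; records whose sequence contains characters outside {A, C, G, U} are
never folded silently — they are quarantined by :func:`filter_cds` with an
explicit reason code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .errors import BoundsError, ConfigError, DomainError, FastaParseError

RNA_ALPHABET = frozenset("ACGU")

DIALECTS = ("ncbi_cds_from_genomic", "plain")

#: reason codes emitted by filter_cds
PSEUDO = "PSEUDO"
TOO_SHORT = "TOO_SHORT"
BAD_ALPHABET = "BAD_ALPHABET"

_TAG_RE = re.compile(r"\[([A-Za-z_]+)=([^\]]*)\]")


@dataclass(frozen=True)
class CdsRecord:
    """One validated coding sequence with parsed header metadata."""

    id: str
    sequence: str
    gene: str = ""
    protein_id: str = ""
    description: str = ""
    is_pseudo: bool = False
    source_file: str = ""


@dataclass(frozen=True)
class Window:
    """A sub-sequence of a CDS under the +1 convention (1-based, inclusive)."""

    cds_id: str
    start: int
    end: int
    sequence: str
    gc_percent: float


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U; no other character is touched."""
    return raw.upper().replace("T", "U")


def read_cds_fasta(
    path: str | Path, dialect: str = "ncbi_cds_from_genomic"
) -> Iterator[CdsRecord]:
    """Stream CdsRecords from a FASTA file.

    The ``ncbi_cds_from_genomic`` dialect parses bracketed ``[tag=value]``
    fields from the description (``gene``, ``protein_id`` and a
    case-insensitive ``pseudo=true`` flag).  The ``plain`` dialect keeps only
    the FASTA id.
    """
    if dialect not in DIALECTS:
        raise ConfigError(f"unknown header dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    _check_leading_garbage(path)
    source = path.name
    for seq_record in SeqIO.parse(str(path), "fasta"):
        sequence = normalize_sequence(str(seq_record.seq))
        gene = ""
        protein_id = ""
        is_pseudo = False
        if dialect == "ncbi_cds_from_genomic":
            for key, value in _TAG_RE.findall(seq_record.description):
                key = key.lower()
                if key == "gene":
                    gene = value
                elif key == "protein_id":
                    protein_id = value
                elif key == "pseudo" and value.lower() == "true":
                    is_pseudo = True
        yield CdsRecord(
            id=seq_record.id,
            sequence=sequence,
            gene=gene,
            protein_id=protein_id,
            description=seq_record.description,
            is_pseudo=is_pseudo,
            source_file=source,
        )


def _check_leading_garbage(path: Path) -> None:
    # SeqIO silently skips text before the first '>'; we refuse it instead.
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: sequence data before first FASTA header at line {lineno}"
                )
            return


@dataclass
class FilterRules:
    """Which checks filter_cds applies. Default minimum length 65 guarantees
    that the full +16..+65 screening window exists in every kept record."""

    pseudo: bool = True
    min_length: int | None = 65
    alphabet: bool = True


@dataclass
class FilterResult:
    kept: list[CdsRecord] = field(default_factory=list)
    rejected: list[tuple[CdsRecord, str]] = field(default_factory=list)
    n_non_aug_start: int = 0  # warning counter only; never a rejection


def filter_cds(records: Iterable[CdsRecord], rules: FilterRules | None = None) -> FilterResult:
    """Partition records into kept / rejected with machine-readable reasons.

    Start-codon identity is deliberately not enforced (bacterial CDSs may
    start GUG/UUG); non-AUG starts are only counted as warnings.
    """
    rules = rules or FilterRules()
    result = FilterResult()
    for rec in records:
        reason = None
        if rules.pseudo and rec.is_pseudo:
            reason = PSEUDO
        elif rules.min_length is not None and len(rec.sequence) < rules.min_length:
            reason = TOO_SHORT
        elif rules.alphabet and not set(rec.sequence) <= RNA_ALPHABET:
            reason = BAD_ALPHABET
        if reason is None:
            if not rec.sequence.startswith("AUG"):
                result.n_non_aug_start += 1
            result.kept.append(rec)
        else:
            result.rejected.append((rec, reason))
    return result


def extract_window(record: CdsRecord, start: int = 16, end: int = 65) -> Window:
    """Inclusive sub-sequence at [start, end] under the +1 convention."""
    if not (1 <= start <= end):
        raise BoundsError(f"invalid window coordinates {start}..{end}")
    if end > len(record.sequence):
        raise BoundsError(
            f"window {start}..{end} exceeds length {len(record.sequence)} of record {record.id}"
        )
    sub = record.sequence[start - 1 : end]
    return Window(
        cds_id=record.id,
        start=start,
        end=end,
        sequence=sub,
        gc_percent=gc_content(sub),
    )


def gc_content(sequence: str) -> float:
    """GC percentage (0-100) of a non-empty A/C/G/U sequence."""
    if not sequence:
        raise DomainError("gc_content of empty sequence is undefined")
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise DomainError(f"gc_content: invalid characters {sorted(bad)}")
    gc = sequence.count("G") + sequence.count("C")
    return 100.0 * gc / len(sequence)


def dedupe_by_window(
    records: Iterable[CdsRecord], start: int = 16, end: int = 65
) -> tuple[list[CdsRecord], list[tuple[CdsRecord, str]]]:
    """Collapse records whose screening windows are identical.

    Returns (unique records, duplicates as (record, kept_id) pairs).  The
    first record carrying a given window, in input order, is kept.
    """
    seen: dict[str, str] = {}
    unique: list[CdsRecord] = []
    dupes: list[tuple[CdsRecord, str]] = []
    for rec in records:
        key = rec.sequence[start - 1 : end]
        if key in seen:
            dupes.append((rec, seen[key]))
        else:
            seen[key] = rec.id
            unique.append(rec)
    return unique, dupes


def write_cds_fasta(records: Iterable[CdsRecord], handle: TextIO) -> None:
    """Write records in the NCBI bracketed-tag dialect (round-trip safe)."""
    for rec in records:
        tags = []
        if rec.gene:
            tags.append(f"[gene={rec.gene}]")
        if rec.protein_id:
            tags.append(f"[protein_id={rec.protein_id}]")
        if rec.is_pseudo:
            tags.append("[pseudo=true]")
        header = rec.id + (" " + " ".join(tags) if tags else "")
        handle.write(f">{header}\n")
        for i in range(0, len(rec.sequence), 70):
            handle.write(rec.sequence[i : i + 70] + "\n")


def write_rejected_tsv(rejected: Iterable[tuple[CdsRecord, str]], handle: TextIO) -> None:
    handle.write("cds_id\treason\tsource_file\n")
    for rec, reason in rejected:
        handle.write(f"{rec.id}\t{reason}\t{rec.source_file}\n")
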