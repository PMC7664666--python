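"""Synthetic fixture "species": CDS FASTA files with planted structure.

The generator emulates an NCBI ``*_cds_from_genomic.fna`` download for one
species: AUG-initiated records at a controllable GC content, into which
perfect stem-loops and G-rich quadruplex motifs are planted at chosen
offsets.  Planting truth travels in a sidecar TSV, never in the FASTA
headers, so the screening pipeline cannot see it.

Defaults mirror the screen's geometry: records of 150 nt (comfortably above
the 65 nt minimum), stems of 20 bp with a 6 nt loop planted at +16 so the
whole 46 nt hairpin sits inside the +16..+65 window, quadruplexes of two
layers (8 engaged Gs).  Quadruplex linkers are drawn from {A, U} so the
planted Gs cannot be sequestered into competing Watson-Crick pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cds_io import CdsRecord
from .errors import ConfigError, DomainError

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

WINDOW_START = 16
WINDOW_END = 65


@dataclass(frozen=True)
class SyntheticSpec:
    n_cds: int = 100
    gc_target: float = 0.5
    n_planted_stems: int = 10
    stem_length: int = 20
    loop_length: int = 6
    stem_offset: int = WINDOW_START
    n_planted_gquads: int = 0
    gquad_layers: int = 2
    gquad_linker_max: int = 1
    n_pseudo: int = 0
    cds_length: int = 150
    seed: int = 42

    def __post_init__(self):
        if not (0.0 <= self.gc_target <= 1.0):
            raise ConfigError("gc_target must be in [0, 1]")
        if self.cds_length < WINDOW_END:
            raise ConfigError(f"cds_length must be >= {WINDOW_END}")
        if self.n_planted_stems and self.stem_offset == WINDOW_START:
            span = 2 * self.stem_length + self.loop_length
            if span > WINDOW_END - WINDOW_START + 1:
                raise ConfigError(
                    f"hairpin of {span} nt does not fit the "
                    f"{WINDOW_END - WINDOW_START + 1} nt window"
                )
        if self.n_planted_gquads and self.gquad_layers < 2:
            raise ConfigError("gquad_layers must be >= 2")


@dataclass(frozen=True)
class PlantTruth:
    cds_id: str
    planted_kind: str  # "stem" | "gquad" | "background"
    start: int  # 1-based planting coordinate, 0 for background
    end: int
    in_window: bool
    detail: str = ""  # e.g. "stem_length=20,loop=6" or "layers=2"


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    # equal split within the GC and AU halves
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(np.array(list("ACGU")), size=n, p=p))


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def make_background_cds(
    length: int, gc: float, rng: np.random.Generator, cds_id: str = "bg"
) -> CdsRecord:
    """AUG followed by i.i.d. nucleotides at the target GC, no planted
    structure; stop codons are not enforced (the screen is frame-agnostic)."""
    if length < WINDOW_END:
        raise DomainError(f"length must be >= {WINDOW_END}")
    if not (0.0 <= gc <= 1.0):
        raise DomainError("gc must be in [0, 1]")
    return CdsRecord(id=cds_id, sequence="AUG" + _random_nt(rng, length - 3, gc))


def make_hairpin_cds(
    spec: SyntheticSpec, rng: np.random.Generator, cds_id: str = "stem"
) -> tuple[CdsRecord, PlantTruth]:
    """Plant a perfect stem-loop (S .. loop .. revcomp(S)) at spec.stem_offset."""
    span = 2 * spec.stem_length + spec.loop_length
    if spec.stem_offset + span - 1 > spec.cds_length:
        raise ConfigError("hairpin exceeds CDS length")
    stem = _random_nt(rng, spec.stem_length, spec.gc_target)
    loop = _random_nt(rng, spec.loop_length, spec.gc_target)
    hairpin = stem + loop + reverse_complement(stem)
    background = make_background_cds(spec.cds_length, spec.gc_target, rng, cds_id).sequence
    start = spec.stem_offset
    seq = background[: start - 1] + hairpin + background[start - 1 + span :]
    truth = PlantTruth(
        cds_id=cds_id,
        planted_kind="stem",
        start=start,
        end=start + span - 1,
        in_window=start >= WINDOW_START and start + span - 1 <= WINDOW_END,
        detail=f"stem_length={spec.stem_length},loop={spec.loop_length}",
    )
    return CdsRecord(id=cds_id, sequence=seq), truth


def gquad_motif(layers: int, rng: np.random.Generator, linker_max: int = 1) -> str:
    """Four G runs of ``layers`` Gs joined by A/U linkers of 1..linker_max nt.

    Short loops are what keeps a quadruplex competitive against hairpin
    alternatives: with two layers the fold is only stable for 1-2 nt loops,
    hence the default of 1.
    """
    if layers < 2:
        raise ConfigError("gquad_layers must be >= 2")
    if not (1 <= linker_max <= 7):
        raise ConfigError("linker_max must be in 1..7")
    g_run = "G" * layers
    parts = [g_run]
    for _ in range(3):
        linker_len = int(rng.integers(1, linker_max + 1))
        linker = "".join(rng.choice(np.array(["A", "U"]), size=linker_len))
        parts.append(linker + g_run)
    return "".join(parts)


def make_gquad_cds(
    spec: SyntheticSpec, rng: np.random.Generator, cds_id: str = "gq", offset: int | None = None
) -> tuple[CdsRecord, PlantTruth]:
    """Plant a quadruplex motif; expected '+' count is 4 x layers when the
    motif lies inside the screening window."""
    offset = spec.stem_offset if offset is None else offset
    motif = gquad_motif(spec.gquad_layers, rng, spec.gquad_linker_max)
    if offset + len(motif) - 1 > spec.cds_length:
        raise ConfigError("quadruplex motif exceeds CDS length")
    background = make_background_cds(spec.cds_length, spec.gc_target, rng, cds_id).sequence
    seq = background[: offset - 1] + motif + background[offset - 1 + len(motif) :]
    end = offset + len(motif) - 1
    truth = PlantTruth(
        cds_id=cds_id,
        planted_kind="gquad",
        start=offset,
        end=end,
        in_window=offset >= WINDOW_START and end <= WINDOW_END,
        detail=f"layers={spec.gquad_layers},expected_plus={4 * spec.gquad_layers}",
    )
    return CdsRecord(id=cds_id, sequence=seq), truth


def make_species_records(spec: SyntheticSpec) -> tuple[list[CdsRecord], list[PlantTruth]]:
    """Generate all records for one fixture species, in shuffled order.

    Record count is exactly spec.n_cds; planted stems, quadruplexes and
    pseudogene-tagged records are drawn from that total.
    """
    n_special = spec.n_planted_stems + spec.n_planted_gquads + spec.n_pseudo
    if n_special > spec.n_cds:
        raise ConfigError("planted + pseudo records exceed n_cds")
    rng = np.random.default_rng(spec.seed)
    records: list[CdsRecord] = []
    truths: list[PlantTruth] = []
    serial = 0

    def next_id() -> str:
        # ids carry no hint of what was planted; truth lives in the sidecar
        nonlocal serial
        serial += 1
        return f"lcl|SYN01_cds_{serial:04d}_1"

    for _ in range(spec.n_planted_stems):
        rec, truth = make_hairpin_cds(spec, rng, cds_id=next_id())
        records.append(_with_tags(rec, serial))
        truths.append(truth)
    for _ in range(spec.n_planted_gquads):
        rec, truth = make_gquad_cds(spec, rng, cds_id=next_id())
        records.append(_with_tags(rec, serial))
        truths.append(truth)
    for _ in range(spec.n_pseudo):
        rec = make_background_cds(spec.cds_length, spec.gc_target, rng, next_id())
        records.append(_with_tags(rec, serial, pseudo=True))
        truths.append(PlantTruth(rec.id, "background", 0, 0, False, "pseudo"))
    for _ in range(spec.n_cds - n_special):
        rec = make_background_cds(spec.cds_length, spec.gc_target, rng, next_id())
        records.append(_with_tags(rec, serial))
        truths.append(PlantTruth(rec.id, "background", 0, 0, False))

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truths = [truths[i] for i in order]
    return records, truths


def _with_tags(rec: CdsRecord, serial: int, pseudo: bool = False) -> CdsRecord:
    from dataclasses import replace

    return replace(
        rec,
        gene=f"syng{serial:04d}",
        protein_id=f"SYNP{serial:04d}",
        is_pseudo=pseudo,
    )


def make_species_fixture(
    spec: SyntheticSpec, fasta_path: str | Path, truth_path: str | Path
) -> tuple[Path, Path]:
    """Write the fixture FASTA (NCBI header dialect) and the truth TSV."""
    from .cds_io import write_cds_fasta

    fasta_path = Path(fasta_path)
    truth_path = Path(truth_path)
    records, truths = make_species_records(spec)
    with open(fasta_path, "w") as fh:
        write_cds_fasta(records, fh)
    with open(truth_path, "w") as fh:
        fh.write("cds_id\tplanted_kind\tstart\tend\tin_window\tdetail\n")
        for t in truths:
            fh.write(
                f"{t.cds_id}\t{t.planted_kind}\t{t.start}\t{t.end}\t"
                f"{str(t.in_window).lower()}\t{t.detail}\n"
            )
    return fasta_path, truth_path
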