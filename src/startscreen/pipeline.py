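"""End-to-end screen: read -> filter -> window -> fold -> null -> select ->
G-quadruplex accounting -> GO annotation -> reports.

Given the same inputs, configuration and seed, every output file is
byte-identical across runs: per-window RNG streams are derived from
(seed, CDS id), floats are formatted with fixed precision, and JSON keys
are sorted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import cds_io, go_annotation, gquad
from .cds_io import FilterRules
from .errors import StartScreenError
from .folding import DEFAULT_ORACLE_SPEC, FolderSpec, get_folder
from .null_model import null_mfe_stats
from .selection import (
    ScreenRecord,
    SelectionConfig,
    SpeciesSummary,
    select_structures,
    summarize_gc,
)

logger = logging.getLogger("startscreen")


@dataclass
class RunConfig:
    cds_paths: list[str]
    species: str = "species"
    out_dir: str = "startscreen_out"
    folder: FolderSpec = field(default_factory=lambda: DEFAULT_ORACLE_SPEC)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    filter_rules: FilterRules = field(default_factory=FilterRules)
    seed: int = 1
    dialect: str = "ncbi_cds_from_genomic"
    uniprot_reviewed: str | None = None
    uniprot_unreviewed: str | None = None
    dedupe_window: bool = False


@dataclass
class RunResult:
    summary: SpeciesSummary
    records: list[ScreenRecord]
    counters: dict[str, int]
    out_dir: Path


def run_screen(config: RunConfig) -> RunResult:
    """Execute the full screen and write all report files into out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_config(config, out_dir / "config.json")

    all_records = []
    for path in config.cds_paths:
        if not Path(path).exists():
            raise StartScreenError(f"input FASTA not found: {path}")
        all_records.extend(cds_io.read_cds_fasta(path, dialect=config.dialect))

    filt = cds_io.filter_cds(all_records, config.filter_rules)
    kept = filt.kept
    counters = {
        "n_input": len(all_records),
        "n_kept": len(kept),
        "n_rejected": len(filt.rejected),
        "n_non_aug_start": filt.n_non_aug_start,
        "n_window_duplicates": 0,
    }
    with open(out_dir / "rejected.tsv", "w") as fh:
        cds_io.write_rejected_tsv(filt.rejected, fh)

    sel = config.selection
    if config.dedupe_window:
        kept, dupes = cds_io.dedupe_by_window(kept, sel.window_start, sel.window_end)
        counters["n_window_duplicates"] = len(dupes)
        with open(out_dir / "window_duplicates.tsv", "w") as fh:
            fh.write("cds_id\tduplicate_of\n")
            for rec, kept_id in dupes:
                fh.write(f"{rec.id}\t{kept_id}\n")

    engine = get_folder(config.folder)
    drafts: list[ScreenRecord] = []
    for rec in kept:
        window = cds_io.extract_window(rec, sel.window_start, sel.window_end)
        fold = engine.fold(window.sequence, window_id=rec.id)
        null = null_mfe_stats(
            window.sequence,
            n=sel.n_shuffles,
            folder=engine,
            seed=config.seed,
            window_id=rec.id,
            mfe_struc=fold.mfe_struc,
        )
        drafts.append(
            ScreenRecord(
                cds_id=rec.id,
                gene=rec.gene,
                protein_id=rec.protein_id,
                window=window,
                fold=fold,
                null=null,
            )
        )

    gc_pooled = summarize_gc(kept) if kept else None
    finalized, summary = select_structures(
        drafts, sel, species=config.species, gc_percent_cds=gc_pooled
    )
    selected = [r for r in finalized if r.selected]

    _write_records_tsv(finalized, out_dir / "records.tsv", sel)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "gquad_histogram.tsv", "w") as fh:
        gquad.write_histogram_tsv(config.species, summary.gquad_histogram, fh)
    with open(out_dir / "structures.txt", "w") as fh:
        write_structure_report(selected, fh, window=(sel.window_start, sel.window_end))

    if config.uniprot_reviewed or config.uniprot_unreviewed:
        index = go_annotation.GoIndex()
        # unreviewed first so reviewed entries win on conflict
        if config.uniprot_unreviewed:
            for ann in go_annotation.parse_uniprot_go(config.uniprot_unreviewed, reviewed=False):
                index.add(ann)
        if config.uniprot_reviewed:
            for ann in go_annotation.parse_uniprot_go(config.uniprot_reviewed, reviewed=True):
                index.add(ann)
        annotated = go_annotation.map_cds_go(selected, index)
        with open(out_dir / "go_terms.tsv", "w") as fh:
            go_annotation.write_ranked_terms_tsv(annotated, fh)
        counters["n_unannotated_selected"] = sum(
            1 for a in annotated if a.provenance == "UNANNOTATED"
        )

    for name, value in counters.items():
        logger.info("%s: %d", name, value)
    return RunResult(summary=summary, records=finalized, counters=counters, out_dir=out_dir)


def _fmt_ratio(ratio: float) -> str:
    return "inf" if math.isinf(ratio) else f"{ratio:.4f}"


def _write_records_tsv(records: list[ScreenRecord], path: Path, sel: SelectionConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# coordinates are 1-based inclusive; +1 = first CDS nucleotide; "
            f"window {sel.window_start}..{sel.window_end}\n"
        )
        fh.write(
            "cds_id\tgene\twindow_sequence\tstructure\tmfe_struc\tmfe_rand_mean\t"
            "ratio\tgc_percent\tgquad_residues\tpassed_ratio\tpassed_quantile\tselected\n"
        )
        for r in records:
            fh.write(
                f"{r.cds_id}\t{r.gene}\t{r.window.sequence}\t{r.fold.structure}\t"
                f"{r.fold.mfe_struc:.2f}\t{r.null.mfe_rand_mean:.4f}\t"
                f"{_fmt_ratio(r.null.ratio)}\t{r.window.gc_percent:.2f}\t"
                f"{r.fold.gquad_residues}\t{int(r.passed_ratio)}\t"
                f"{int(r.passed_quantile)}\t{int(r.selected)}\n"
            )


def write_structure_report(selected: list[ScreenRecord], handle, window=(16, 65)) -> None:
    """FASTA-like triplet blocks: >id / window sequence / structure (energy)."""
    handle.write(
        f"# selected structures, window +{window[0]}..+{window[1]} "
        f"(+1 = first CDS nucleotide)\n"
    )
    for r in selected:
        handle.write(f">{r.cds_id}\n{r.window.sequence}\n")
        handle.write(f"{r.fold.structure} ({r.fold.mfe_struc:.1f})\n")


def _write_config(config: RunConfig, path: Path) -> None:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return str(obj)

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True, default=encode)
        fh.write("\n")
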