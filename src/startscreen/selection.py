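"""Two-stage structure selection and per-species summaries.

Stage 1 keeps windows whose MFE_struc / mean MFE_rand ratio is at least
``ratio_min`` (default 2, inclusive).  Stage 2 additionally requires a
window's MFE_struc to be equal to or below the species-level empirical 0.25
quantile of the MFE_struc distribution of all folded windows, so that only
the most stable quartile of candidate structures survives.  Setting
``quantile_population="ratio_passed"`` restricts the quantile population to
stage-1 survivors for sensitivity analysis.

Both thresholds are inclusive, so records sitting exactly on a boundary are
kept.  Selection is a set operation: input order never changes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cds_io import CdsRecord, Window
from .errors import ConfigError, DomainError
from .folding import FoldResult
from .null_model import NullResult

GQUAD_MIN_RESIDUES = 8  # two stacked quartets, the engine's minimum


@dataclass(frozen=True)
class SelectionConfig:
    ratio_min: float = 2.0
    quantile: float = 0.25
    window_start: int = 16
    window_end: int = 65
    n_shuffles: int = 100
    quantile_population: str = "all"  # or "ratio_passed"

    def __post_init__(self):
        if not (0 < self.quantile <= 1):
            raise ConfigError("quantile must be in (0, 1]")
        if self.ratio_min <= 0:
            raise ConfigError("ratio_min must be > 0")
        if self.quantile_population not in ("ratio_passed", "all"):
            raise ConfigError("quantile_population must be 'ratio_passed' or 'all'")


@dataclass(frozen=True)
class ScreenRecord:
    """Join of CDS, window, fold and null results plus selection flags."""

    cds_id: str
    gene: str
    protein_id: str
    window: Window
    fold: FoldResult
    null: NullResult
    passed_ratio: bool = False
    passed_quantile: bool = False
    selected: bool = False

    @property
    def is_gquad(self) -> bool:
        return self.fold.gquad_residues >= GQUAD_MIN_RESIDUES


@dataclass
class SpeciesSummary:
    species: str
    n_cds_analyzed: int = 0
    n_selected: int = 0
    n_gquad_selected: int = 0
    percent_selected: float = 0.0
    percent_gquad: float = 0.0
    gc_percent_cds: float | None = None
    mfe_quantile_threshold: float | None = None
    top_quartile_min_mfe: float | None = None
    gquad_histogram: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        """JSON-ready view; percentages to two decimals, energies to one."""
        rnd2 = lambda x: None if x is None else round(x, 2)
        return {
            "species": self.species,
            "n_cds_analyzed": self.n_cds_analyzed,
            "n_selected": self.n_selected,
            "n_gquad_selected": self.n_gquad_selected,
            "percent_selected": rnd2(self.percent_selected),
            "percent_gquad": rnd2(self.percent_gquad),
            "gc_percent_cds": rnd2(self.gc_percent_cds),
            "mfe_quantile_threshold": None
            if self.mfe_quantile_threshold is None
            else round(self.mfe_quantile_threshold, 1),
            "top_quartile_min_mfe": None
            if self.top_quartile_min_mfe is None
            else round(self.top_quartile_min_mfe, 1),
            "gquad_histogram": {str(k): v for k, v in sorted(self.gquad_histogram.items())},
        }


def quantile_threshold(mfe_values, q: float) -> float:
    """Linear-interpolation empirical quantile of a non-empty energy list."""
    values = np.asarray(list(mfe_values), dtype=float)
    if values.size == 0:
        raise DomainError("quantile of empty list is undefined")
    return float(np.quantile(values, q))


def select_structures(
    records: list[ScreenRecord],
    config: SelectionConfig | None = None,
    species: str = "",
    gc_percent_cds: float | None = None,
) -> tuple[list[ScreenRecord], SpeciesSummary]:
    """Apply the ratio filter then the species-level quantile filter.

    Returns finalized records (flags set, same order as input) and the
    species summary including the G-quadruplex histogram of selected records.
    """
    config = config or SelectionConfig()
    ratio_flags = [r.null.ratio >= config.ratio_min for r in records]
    if config.quantile_population == "ratio_passed":
        population = [r.fold.mfe_struc for r, ok in zip(records, ratio_flags) if ok]
    else:
        population = [r.fold.mfe_struc for r in records]
    threshold = quantile_threshold(population, config.quantile) if population else None

    finalized: list[ScreenRecord] = []
    for rec, ok in zip(records, ratio_flags):
        passed_q = threshold is not None and rec.fold.mfe_struc <= threshold
        finalized.append(
            replace(rec, passed_ratio=ok, passed_quantile=passed_q, selected=ok and passed_q)
        )

    selected = [r for r in finalized if r.selected]
    gquad_selected = [r for r in selected if r.is_gquad]
    histogram: dict[int, int] = {}
    for r in gquad_selected:
        histogram[r.fold.gquad_residues] = histogram.get(r.fold.gquad_residues, 0) + 1

    n = len(records)
    summary = SpeciesSummary(
        species=species,
        n_cds_analyzed=n,
        n_selected=len(selected),
        n_gquad_selected=len(gquad_selected),
        percent_selected=100.0 * len(selected) / n if n else 0.0,
        percent_gquad=100.0 * len(gquad_selected) / n if n else 0.0,
        gc_percent_cds=gc_percent_cds,
        mfe_quantile_threshold=threshold,
        top_quartile_min_mfe=min((r.fold.mfe_struc for r in selected), default=None),
        gquad_histogram=histogram,
    )
    return finalized, summary


def summarize_gc(records: list[CdsRecord]) -> float:
    """Pooled GC percentage over the concatenated kept CDS nucleotides.

    Pooling weights long CDSs more than a mean of per-CDS percentages would.
    """
    if not records:
        raise DomainError("summarize_gc of empty record list is undefined")
    gc = 0
    total = 0
    for rec in records:
        gc += rec.sequence.count("G") + rec.sequence.count("C")
        total += len(rec.sequence)
    return 100.0 * gc / total
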