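"""G-quadruplex accounting for selected structures.

A G-quadruplex engages 4 x L guanines (L stacked quartets of four Gs each);
the folding engine marks each engaged G with '+' in the dot-bracket string,
so the residue count is simply the number of '+' characters.  The smallest
quadruplex the engine emits has two layers, i.e. 8 residues, which is also
the classification threshold for ``is_gquad``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .selection import GQUAD_MIN_RESIDUES, ScreenRecord

#: lower edges of the categorical residue-count bins
BIN_EDGES = (8, 12, 16, 20, 24, 28, 32)


@dataclass(frozen=True)
class GQuadInfo:
    window_id: str
    g_residues: int
    bin: str
    layers: int | None  # g_residues / 4, or None when irregular

    @property
    def is_gquad(self) -> bool:
        return self.g_residues >= GQUAD_MIN_RESIDUES

    @property
    def irregular(self) -> bool:
        return self.layers is None


def count_gquad_residues(structure: str) -> int:
    """Number of quadruplex-engaged G residues ('+' characters)."""
    return structure.count("+")


def classify_gquad(window_id: str, g_residues: int) -> GQuadInfo:
    if g_residues < 0:
        raise ValueError("g_residues must be >= 0")
    if g_residues >= BIN_EDGES[-1]:
        label = f"{BIN_EDGES[-1]}+"
    else:
        below = [e for e in BIN_EDGES if e <= g_residues]
        label = str(below[-1]) if below else "<8"
    layers = g_residues // 4 if g_residues % 4 == 0 else None
    return GQuadInfo(window_id=window_id, g_residues=g_residues, bin=label, layers=layers)


def gquad_histogram(records: Iterable[ScreenRecord]) -> dict[int, int]:
    """Exact residue-count histogram over quadruplex-bearing records.

    Keys are exact '+' counts; total frequency equals the number of records
    with at least the minimum 8 engaged residues.  Any categorical binning
    (8/12/16/20 or 8/12/16/24/32) is derivable from the exact counts.
    """
    hist: dict[int, int] = {}
    for rec in records:
        g = rec.fold.gquad_residues
        if g >= GQUAD_MIN_RESIDUES:
            hist[g] = hist.get(g, 0) + 1
    return hist


def write_histogram_tsv(species: str, hist: dict[int, int], handle) -> None:
    handle.write("species\tg_residues\tfrequency\n")
    for g in sorted(hist):
        handle.write(f"{species}\t{g}\t{hist[g]}\n")
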