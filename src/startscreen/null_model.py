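"""Shuffle-based null distribution of window MFE and the selection ratio.

The selection statistic is MFE_struc / mean(MFE_rand), where MFE_rand values
come from folding mononucleotide shuffles of the same window (plain
Fisher-Yates permutations, so the nucleotide multiset is conserved exactly).
A window whose native fold is at least twice as stable as the average fold
of its own shuffled composition is considered reliably structured.

Per-window RNG streams are derived from (global seed, window id), so results
are independent of the order in which windows are processed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .folding import FolderSpec, get_folder

RATIO_INF = math.inf


@dataclass(frozen=True)
class NullResult:
    window_id: str
    n_shuffles: int
    mfe_rand_mean: float
    ratio: float
    seed: int


def window_rng(seed: int, window_id: str) -> np.random.Generator:
    """Deterministic per-window generator derived from (seed, window id)."""
    key = zlib.crc32(window_id.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Uniform mononucleotide permutation of ``sequence``."""
    chars = np.array(list(sequence))
    rng.shuffle(chars)
    return "".join(chars)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson style Euler walk).

    Offered for sensitivity analysis only; the default null uses plain
    mononucleotide permutation.
    """
    if len(sequence) < 3:
        return sequence
    # multigraph of dinucleotide edges; retry random Euler walks until one
    # consumes every edge (rejection sampling over edge orderings)
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(sequence) - 1
    for _ in range(200):
        trial = {a: [bs[i] for i in rng.permutation(len(bs))] for a, bs in edges.items()}
        out = [sequence[0]]
        cur = sequence[0]
        while trial.get(cur):
            cur = trial[cur].pop()
            out.append(cur)
        if len(out) == n_edges + 1:
            return "".join(out)
    return shuffle_sequence(sequence, rng)


def mfe_ratio(mfe_struc: float, mfe_rand_mean: float) -> float:
    """MFE_struc / mean MFE_rand with explicit zero-energy policy.

    Both energies must be <= 0.  An unstructured native window (MFE_struc ==
    0) gets ratio 0 and is never selected; a structured window whose shuffles
    are all unstructured (mean == 0) gets +inf and passes any threshold.
    """
    if mfe_struc > 0 or mfe_rand_mean > 0:
        raise DomainError(
            f"energies must be <= 0 kcal/mol, got ({mfe_struc}, {mfe_rand_mean})"
        )
    if mfe_struc == 0:
        return 0.0
    if mfe_rand_mean == 0:
        return RATIO_INF
    return mfe_struc / mfe_rand_mean


def null_mfe_stats(
    sequence: str,
    n: int,
    folder: FolderSpec | object,
    seed: int,
    window_id: str = "",
    mfe_struc: float | None = None,
) -> NullResult:
    """Fold ``n`` independent shuffles of ``sequence`` and summarize.

    ``folder`` may be a FolderSpec or an already-constructed engine object.
    If ``mfe_struc`` is None the native window is folded too (one extra call).
    """
    if n < 1:
        raise DomainError("n_shuffles must be >= 1")
    engine = get_folder(folder) if isinstance(folder, FolderSpec) else folder
    rng = window_rng(seed, window_id)
    if mfe_struc is None:
        mfe_struc = engine.fold(sequence, window_id=window_id).mfe_struc
    energies = np.empty(n, dtype=float)
    for i in range(n):
        shuffled = shuffle_sequence(sequence, rng)
        energies[i] = engine.fold(shuffled, window_id=f"{window_id}#shuf{i}").mfe_struc
    mean = float(energies.mean())
    return NullResult(
        window_id=window_id,
        n_shuffles=n,
        mfe_rand_mean=mean,
        ratio=mfe_ratio(mfe_struc, mean),
        seed=seed,
    )
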