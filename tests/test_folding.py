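"""Oracle folder and structure parsing.

The brute-force reference used here enumerates every legal set of
non-crossing pairs explicitly (exponential), independently of the dynamic
program it checks.
"""

import itertools

import numpy as np
import pytest

from startscreen.errors import ConfigError, DomainError, StructureFormatError
from startscreen.folding import (
    DEFAULT_ORACLE_SPEC,
    FolderSpec,
    NussinovFolder,
    fold_mfe,
    get_folder,
    parse_structure,
)

PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_pair_sets(seq, min_loop):
    """All legal (non-crossing, hairpin-constrained) pair sets of seq."""

    def rec(i, j):
        if i >= j:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        return out

    return rec(0, len(seq) - 1)


def count_helices(pairs):
    pairs = set(pairs)
    return sum(1 for (i, j) in pairs if (i - 1, j + 1) not in pairs)


def brute_force_min_energy(seq, min_loop, pair_score=-1.0, helix_penalty=0.0):
    best = 0.0
    for pairs in enumerate_pair_sets(seq, min_loop):
        e = pair_score * len(pairs) + helix_penalty * count_helices(pairs)
        best = min(best, e)
    return best


class TestNussinovOracle:
    @pytest.mark.parametrize(
        "seq,kwargs,structure,mfe",
        [
            ("GGGAAACCC", {}, "(((...)))", -3.0),
            ("ACGU", {}, "....", 0.0),
            ("A" * 50, {}, "." * 50, 0.0),
            ("AAAA", {"min_loop": 0}, "....", 0.0),
            ("GCGC", {"min_loop": 0}, "()()", -2.0),
        ],
    )
    def test_known_optima(self, seq, kwargs, structure, mfe):
        r = NussinovFolder(**kwargs).fold(seq)
        assert r.structure == structure
        assert r.mfe_struc == mfe

    def test_mfe_equals_negative_max_pair_count(self, oracle, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 30))))
            r = oracle.fold(seq)
            assert r.mfe_struc == -oracle.max_pairs(seq)

    @pytest.mark.parametrize("helix_penalty", [0.0, 2.0])
    def test_matches_brute_force_enumeration(self, rng, helix_penalty):
        """Exact DP equals exhaustive enumeration for short sequences."""
        folder = NussinovFolder(helix_penalty=helix_penalty)
        # all 4-mers exhaustively, plus random sequences up to length 10
        seqs = ["".join(t) for t in itertools.product("ACGU", repeat=4)]
        seqs += [
            "".join(rng.choice(list("ACGU"), size=int(rng.integers(5, 11))))
            for _ in range(60)
        ]
        for seq in seqs:
            expected = brute_force_min_energy(seq, folder.min_loop, -1.0, helix_penalty)
            got = folder.fold(seq)
            assert got.mfe_struc == pytest.approx(expected), seq
            # emitted structure must itself attain the reported energy
            pairs, _ = parse_structure(got.structure)
            e = -len(pairs) + helix_penalty * count_helices(
                {(i - 1, j - 1) for i, j in pairs}
            )
            assert e == pytest.approx(got.mfe_struc)

    def test_structure_invariants_on_fuzz(self, rng):
        folder = get_folder(DEFAULT_ORACLE_SPEC)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGU"), size=50))
            r = folder.fold(seq)
            assert len(r.structure) == 50
            assert r.mfe_struc <= 0
            pairs, gq = parse_structure(r.structure)  # raises if unbalanced
            assert gq == 0  # oracle never emits '+'
            for i, j in pairs:
                assert (seq[i - 1], seq[j - 1]) in PAIRABLE

    def test_traceback_is_deterministic(self, oracle):
        seq = "GCGCAUAUGCGCAUAUGCGC"
        assert oracle.fold(seq).structure == oracle.fold(seq).structure

    def test_invalid_alphabet_rejected(self, oracle):
        with pytest.raises(DomainError):
            oracle.fold("ACGT")

    @pytest.mark.parametrize(
        "kwargs", [{"pair_score": 1.0}, {"min_loop": -1}, {"helix_penalty": -1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            NussinovFolder(**kwargs)


class TestFoldMfe:
    def test_unknown_engine_is_config_error(self):
        with pytest.raises(ConfigError):
            fold_mfe("ACGU", FolderSpec("zuker"))

    def test_oracle_engine_through_spec(self):
        r = fold_mfe("GGGAAACCC", FolderSpec("nussinov_oracle"))
        assert r.mfe_struc == -3.0
        assert "nussinov" in r.folder_name


class TestParseStructure:
    def test_nested_pairs_one_based(self):
        pairs, gq = parse_structure("((...))")
        assert pairs == {(1, 7), (2, 6)}
        assert gq == 0

    def test_gquad_residue_count(self):
        pairs, gq = parse_structure("..++..++..++..++..")
        assert pairs == set()
        assert gq == 8

    def test_single_dot(self):
        assert parse_structure(".") == (set(), 0)

    @pytest.mark.parametrize(
        "structure,index", [("())", 3), ("((.)", 1), (".x.", 2)]
    )
    def test_malformed_reports_first_offending_index(self, structure, index):
        with pytest.raises(StructureFormatError) as exc:
            parse_structure(structure)
        assert exc.value.index == index
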