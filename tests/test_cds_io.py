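import io

import pytest
from hypothesis import given, strategies as st

from startscreen import cds_io
from startscreen.cds_io import (
    BAD_ALPHABET,
    PSEUDO,
    TOO_SHORT,
    CdsRecord,
    FilterRules,
    extract_window,
    filter_cds,
    gc_content,
    read_cds_fasta,
    write_cds_fasta,
)
from startscreen.errors import BoundsError, ConfigError, DomainError, FastaParseError


def _write(tmp_path, text, name="in.fna"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCdsFasta:
    def test_ncbi_dialect_parses_bracketed_tags(self, tmp_path):
        p = _write(
            tmp_path,
            ">lcl|NC_1.1_cds_P1_1 [gene=abc] [protein_id=P1] [pseudo=true]\nATGGGC\n",
        )
        (rec,) = read_cds_fasta(p)
        assert rec.gene == "abc"
        assert rec.protein_id == "P1"
        assert rec.is_pseudo
        assert rec.sequence == "AUGGGC"
        assert rec.source_file == "in.fna"

    def test_pseudo_tag_case_insensitive(self, tmp_path):
        p = _write(tmp_path, ">x [PSEUDO=True]\natg\n")
        (rec,) = read_cds_fasta(p)
        assert rec.is_pseudo

    def test_plain_dialect_normalizes_case_and_t(self, tmp_path):
        p = _write(tmp_path, ">seq1\natg\n")
        (rec,) = read_cds_fasta(p, dialect="plain")
        assert rec.id == "seq1"
        assert rec.gene == ""
        assert rec.sequence == "AUG"

    def test_empty_file_yields_empty_stream(self, tmp_path):
        p = _write(tmp_path, "")
        assert list(read_cds_fasta(p)) == []

    def test_sequence_before_header_is_parse_error_with_line(self, tmp_path):
        p = _write(tmp_path, "ACGT\n>seq1\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            list(read_cds_fasta(p))

    def test_unknown_dialect_is_config_error(self, tmp_path):
        p = _write(tmp_path, ">a\nACGT\n")
        with pytest.raises(ConfigError):
            list(read_cds_fasta(p, dialect="genbank"))

    def test_roundtrip_preserves_fields(self, tmp_path):
        records = [
            CdsRecord(id="a1", sequence="AUG" + "GC" * 40, gene="g1", protein_id="P1"),
            CdsRecord(id="a2", sequence="AUG" + "AU" * 40, is_pseudo=True),
        ]
        buf = io.StringIO()
        write_cds_fasta(records, buf)
        p = _write(tmp_path, buf.getvalue(), "rt.fna")
        back = list(read_cds_fasta(p))
        for orig, new in zip(records, back):
            assert (orig.id, orig.sequence, orig.gene, orig.protein_id, orig.is_pseudo) == (
                new.id, new.sequence, new.gene, new.protein_id, new.is_pseudo
            )


class TestFilterCds:
    @pytest.mark.parametrize(
        "record,reason",
        [
            (CdsRecord(id="p", sequence="AUG" + "A" * 70, is_pseudo=True), PSEUDO),
            (CdsRecord(id="s", sequence="A" * 64), TOO_SHORT),
            (CdsRecord(id="n", sequence="AUG" + "N" * 70), BAD_ALPHABET),
        ],
    )
    def test_rejection_reasons(self, record, reason):
        result = filter_cds([record])
        assert result.kept == []
        assert result.rejected == [(record, reason)]

    def test_length_65_boundary_is_kept(self):
        rec = CdsRecord(id="ok", sequence="AUG" + "A" * 62)
        result = filter_cds([rec])
        assert result.kept == [rec]
        # every kept record supports the full default window
        assert extract_window(rec).sequence == rec.sequence[15:65]

    def test_non_aug_start_is_warning_not_rejection(self):
        rec = CdsRecord(id="gug", sequence="GUG" + "A" * 70)
        result = filter_cds([rec])
        assert result.kept == [rec]
        assert result.n_non_aug_start == 1

    def test_rejected_tsv_lists_reason_codes(self):
        rec = CdsRecord(id="p", sequence="AUGA", is_pseudo=True, source_file="f.fna")
        result = filter_cds([rec])
        buf = io.StringIO()
        cds_io.write_rejected_tsv(result.rejected, buf)
        assert "p\tPSEUDO\tf.fna" in buf.getvalue()


class TestExtractWindow:
    def test_positions_16_to_65_under_plus_one_convention(self):
        rec = CdsRecord(id="x", sequence="AUG" + "C" * 12 + "G" * 50 + "A" * 10)
        win = extract_window(rec, 16, 65)
        assert win.sequence == "G" * 50
        assert len(win.sequence) == win.end - win.start + 1 == 50
        assert win.gc_percent == 100.0

    def test_start_codon_is_positions_1_to_3(self):
        rec = CdsRecord(id="x", sequence="AUGCCCAAA")
        assert extract_window(rec, 1, 3).sequence == "AUG"

    def test_out_of_bounds_names_record(self):
        rec = CdsRecord(id="short1", sequence="AUGAAA")
        with pytest.raises(BoundsError, match="short1"):
            extract_window(rec, 16, 65)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("AUAU", 0.0), ("GCAU", 50.0)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            gc_content("")

    @given(st.text(alphabet="ACGU", min_size=1, max_size=100))
    def test_composition_conserved(self, seq):
        au = 100.0 * (seq.count("A") + seq.count("U")) / len(seq)
        assert gc_content(seq) + au == pytest.approx(100.0)


def test_dedupe_by_window_keeps_first_and_reports_duplicates():
    a = CdsRecord(id="a", sequence="AUG" + "C" * 12 + "G" * 50 + "A" * 5)
    b = CdsRecord(id="b", sequence="UUU" + "A" * 12 + "G" * 50 + "C" * 5)  # same window
    c = CdsRecord(id="c", sequence="AUG" + "C" * 12 + "A" * 50 + "A" * 5)
    unique, dupes = cds_io.dedupe_by_window([a, b, c])
    assert [r.id for r in unique] == ["a", "c"]
    assert [(r.id, kept) for r, kept in dupes] == [("b", "a")]
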