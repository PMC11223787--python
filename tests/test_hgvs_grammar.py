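import random

import pytest
from hypothesis import given, settings, strategies as st

from hgvsmap.errors import (
    CoordinateError,
    HgvsSyntaxError,
    ReferenceMismatchError,
    ValidationError,
)
from hgvsmap.hgvs_grammar import (
    EditKind,
    HgvsVariant,
    UnsupportedVariant,
    apply_edit,
    format_hgvs,
    parse_hgvs,
    write_fasta_record,
)


class TestParse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("EGFR:p.G796D", ("EGFR", "p", EditKind.SUBSTITUTION, 796, 796, "G", "D")),
            ("BRAF:V600E", ("BRAF", "p", EditKind.SUBSTITUTION, 600, 600, "V", "E")),
            ("BRAF: V600E", ("BRAF", "p", EditKind.SUBSTITUTION, 600, 600, "V", "E")),
            (
                "EGFR:p.Gly796Asp",
                ("EGFR", "p", EditKind.SUBSTITUTION, 796, 796, "G", "D"),
            ),
            (
                "chr7:g.140753336A>T",
                ("chr7", "g", EditKind.SUBSTITUTION, 140753336, 140753336, "A", "T"),
            ),
            ("TX1:c.88T>G", ("TX1", "c", EditKind.SUBSTITUTION, 88, 88, "T", "G")),
            ("X:p.K2del", ("X", "p", EditKind.DELETION, 2, 2, "K", "")),
            ("X:p.Lys2Ter", ("X", "p", EditKind.SUBSTITUTION, 2, 2, "K", "*")),
            ("X:g.5_7del", ("X", "g", EditKind.DELETION, 5, 7, "", "")),
            ("X:g.5_6insACT", ("X", "g", EditKind.INSERTION, 5, 6, "", "ACT")),
            ("X:g.5_7delinsTT", ("X", "g", EditKind.DELINS, 5, 7, "", "TT")),
            ("X:g.5_7dup", ("X", "g", EditKind.DUPLICATION, 5, 7, "", "")),
            ("X:p.K2_M3insQ", ("X", "p", EditKind.INSERTION, 2, 3, "", "Q")),
        ],
    )
    def test_supported_grammar(self, text, expected):
        v = parse_hgvs(text)
        assert isinstance(v, HgvsVariant)
        got = (v.reference, v.level, v.edit_kind, v.start, v.end, v.ref_allele,
               v.alt_allele)
        assert got == expected

    @pytest.mark.parametrize(
        "text,reason",
        [
            ("TX1:c.88+2T>G", "intronic-offset"),
            ("TX1:c.-5A>G", "utr-position"),
            ("BRAF:p.V600fs", "frameshift"),
            ("TX1:c.10A[4]", "repeat"),
        ],
    )
    def test_recognized_but_unsupported(self, text, reason):
        v = parse_hgvs(text)
        assert isinstance(v, UnsupportedVariant)
        assert v.reason == reason

    @pytest.mark.parametrize(
        "text", ["no-separator", "GENE:", ":p.G12D", "GENE:p.12G", "X:g.5A>Z"]
    )
    def test_syntax_errors_carry_offset(self, text):
        with pytest.raises(HgvsSyntaxError) as exc:
            parse_hgvs(text)
        assert exc.value.offset >= 0

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            HgvsVariant("X", "g", EditKind.SUBSTITUTION, 5, 5, "AC", "T")
        with pytest.raises(ValidationError):
            HgvsVariant("X", "g", EditKind.INSERTION, 5, 9, "", "A")


class TestFormat:
    @pytest.mark.parametrize(
        "text",
        [
            "EGFR:p.G796D",
            "chr7:g.140753336A>T",
            "X:g.5_7del",
            "X:g.9del",
            "X:g.5_6insACT",
            "X:g.5_7delinsTT",
            "X:g.5_7dup",
            "X:p.K2del",
            "X:p.K2dup",
            "X:p.K2_M3insQ",
            "X:p.K2_M4delinsRS",
            "X:p.V600=",
        ],
    )
    def test_parse_format_is_canonicalizing_fixpoint(self, text):
        v = parse_hgvs(text)
        assert format_hgvs(v) == text
        assert parse_hgvs(format_hgvs(v)) == v

    def test_three_letter_normalized_to_one(self):
        assert format_hgvs(parse_hgvs("EGFR:p.Gly796Asp")) == "EGFR:p.G796D"
        assert format_hgvs(parse_hgvs("BRAF:V600E")) == "BRAF:p.V600E"


_AA = "ACDEFGHIKLMNPQRSTVWY"


@st.composite
def _variants(draw):
    """Random variants inside the canonical-formatting subset."""
    level = draw(st.sampled_from("gcp"))
    kind = draw(st.sampled_from(list(EditKind)))
    start = draw(st.integers(1, 500))
    ref_name = draw(st.sampled_from(["GENE1", "TX9", "chr5"]))
    if level in "gc":
        alphabet = "ACGT"
        if kind is EditKind.SUBSTITUTION:
            ref = draw(st.sampled_from(alphabet))
            alt = draw(st.sampled_from([b for b in alphabet if b != ref]))
            return HgvsVariant(ref_name, level, kind, start, start, ref, alt)
        end = start if kind is EditKind.INSERTION else draw(
            st.integers(start, start + 5)
        )
        if kind is EditKind.INSERTION:
            alt = draw(st.text(alphabet, min_size=1, max_size=4))
            return HgvsVariant(ref_name, level, kind, start, start + 1, "", alt)
        if kind is EditKind.DELINS:
            alt = draw(st.text(alphabet, min_size=1, max_size=4))
            return HgvsVariant(ref_name, level, kind, start, end, "", alt)
        return HgvsVariant(ref_name, level, kind, start, end)
    # p level
    sref = draw(st.sampled_from(_AA))
    if kind is EditKind.SUBSTITUTION:
        alt = draw(st.sampled_from(_AA + "*"))
        return HgvsVariant(ref_name, "p", kind, start, start, sref, alt)
    if kind is EditKind.INSERTION:
        eref = draw(st.sampled_from(_AA))
        alt = draw(st.text(_AA, min_size=1, max_size=3))
        return HgvsVariant(
            ref_name, "p", kind, start, start + 1, "", alt,
            start_ref=sref, end_ref=eref,
        )
    single = draw(st.booleans())
    end = start if single else draw(st.integers(start + 1, start + 4))
    eref = sref if single else draw(st.sampled_from(_AA))
    full_ref = sref if single else ""
    alt = (
        draw(st.text(_AA, min_size=1, max_size=3))
        if kind is EditKind.DELINS
        else ""
    )
    return HgvsVariant(
        ref_name, "p", kind, start, end, full_ref, alt,
        start_ref=sref, end_ref=eref,
    )


class TestRoundTripProperty:
    @settings(max_examples=300, derandomize=True)
    @given(_variants())
    def test_parse_inverts_format(self, variant):
        assert parse_hgvs(format_hgvs(variant)) == variant


class TestApplyEdit:
    def test_substitution(self):
        assert apply_edit("MKT", parse_hgvs("X:p.K2R")) == "MRT"

    def test_single_deletion(self):
        assert apply_edit("MKT", parse_hgvs("X:p.K2del")) == "MT"

    def test_insertion_and_delins_and_dup(self):
        assert apply_edit("MKT", parse_hgvs("X:p.M1_K2insWW")) == "MWWKT"
        assert apply_edit("MKT", parse_hgvs("X:p.K2_T3delinsA")) == "MA"
        assert apply_edit("MKT", parse_hgvs("X:p.K2dup")) == "MKKT"

    def test_ref_mismatch_never_edits_silently(self):
        with pytest.raises(ReferenceMismatchError) as exc:
            apply_edit("MKT", parse_hgvs("X:p.R2del"))
        assert exc.value.expected == "R"
        assert exc.value.observed == "K"

    def test_out_of_range(self):
        with pytest.raises(CoordinateError):
            apply_edit("MKT", parse_hgvs("X:p.K9del"))

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_string_surgery_oracle(self, data):
        """Random valid edits equal naive prefix + alt + suffix splicing."""
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
        start = rng.randint(1, len(seq) - 1)
        end = rng.randint(start, min(len(seq), start + 4))
        kind = rng.choice(list(EditKind))
        alt = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3)))
        if kind is EditKind.SUBSTITUTION:
            ref = seq[start - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            v = HgvsVariant("X", "g", kind, start, start, ref, alt)
            expect = seq[: start - 1] + alt + seq[start:]
        elif kind is EditKind.DELETION:
            v = HgvsVariant("X", "g", kind, start, end, seq[start - 1 : end], "")
            expect = seq[: start - 1] + seq[end:]
        elif kind is EditKind.INSERTION:
            v = HgvsVariant("X", "g", kind, start, start + 1, "", alt)
            expect = seq[:start] + alt + seq[start:]
        elif kind is EditKind.DELINS:
            v = HgvsVariant("X", "g", kind, start, end, seq[start - 1 : end], alt)
            expect = seq[: start - 1] + alt + seq[end:]
        else:
            v = HgvsVariant("X", "g", kind, start, end, seq[start - 1 : end], "")
            expect = seq[:end] + seq[start - 1 : end] + seq[end:]
        assert apply_edit(seq, v) == expect

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_corrupted_ref_allele_always_raises(self, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        seq = "".join(rng.choice("ACGT") for _ in range(20))
        start = rng.randint(1, 20)
        wrong = rng.choice([b for b in "ACGT" if b != seq[start - 1]])
        alt = rng.choice([b for b in "ACGT" if b != wrong])
        v = HgvsVariant("X", "g", EditKind.SUBSTITUTION, start, start, wrong, alt)
        with pytest.raises(ReferenceMismatchError):
            apply_edit(seq, v)


class TestFastaRecord:
    def test_minimal(self):
        assert write_fasta_record("x", "MKT") == ">x\nMKT\n"

    def test_wrap_rule_at_61_residues(self):
        text = write_fasta_record("x", "A" * 61)
        lines = text.splitlines()
        assert [len(x) for x in lines[1:]] == [60, 1]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            write_fasta_record("x", "")

    def test_round_trip_through_fasta_loader(self, tmp_path):
        from hgvsmap.reference_model import load_fasta

        p = tmp_path / "r.fa"
        p.write_text(write_fasta_record("h", "ACGT" * 40))
        assert load_fasta(str(p)).sequences["h"] == "ACGT" * 40
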