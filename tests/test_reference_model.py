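import random

import pytest

from hgvsmap.errors import (
    AlphabetError,
    CoordinateError,
    FileLoadError,
    TranslationError,
    UnknownChromosomeError,
    UnknownGeneError,
    ValidationError,
)
from hgvsmap.fixtures import make_toy_reference, oracle_translate
from hgvsmap.reference_model import (
    GenomeAssembly,
    TranscriptModel,
    get_genomic_sequence,
    get_protein_sequence,
    load_fasta,
    load_gene_symbols,
    load_transcripts,
    reverse_complement,
    select_transcript,
    write_fasta,
    write_transcripts_tsv,
)


def _tx(**kw):
    base = dict(
        transcript_id="T1",
        gene_symbol="G1",
        assembly="toy",
        chrom="chr1",
        strand="+",
        exons=[(11, 19)],
        cds_start_g=11,
        cds_end_g=19,
        is_mane=False,
    )
    base.update(kw)
    return TranscriptModel(**base)


class TestFastaIO:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        asm = load_fasta(str(p))
        assert asm.sequences["chr1"] == "ACGT"

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nGGGG\n")
        with pytest.raises(FileLoadError, match="duplicate"):
            load_fasta(str(p))

    def test_non_iupac_character_names_offset(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXT\n")
        with pytest.raises(FileLoadError, match="offset 2"):
            load_fasta(str(p))

    def test_write_load_round_trip(self, toy, tmp_path):
        path = tmp_path / "genome.fa"
        write_fasta(toy.assembly, str(path))
        again = load_fasta(str(path))
        assert again.sequences == toy.assembly.sequences

    def test_region_headers_create_window(self, tmp_path):
        p = tmp_path / "w.fa"
        p.write_text(">chr9:101-108\nAACCGGTT\n")
        asm = load_fasta(str(p), region_headers=True)
        assert asm.offset("chr9") == 101
        assert get_genomic_sequence(asm, "chr9", 103, 105) == "CCG"
        with pytest.raises(CoordinateError):
            get_genomic_sequence(asm, "chr9", 1, 5)


class TestSequenceAccess:
    def test_substring_and_reverse_complement(self):
        asm = GenomeAssembly("t", {"chr1": "ACGTA"})
        assert get_genomic_sequence(asm, "chr1", 2, 4, "+") == "CGT"
        assert get_genomic_sequence(asm, "chr1", 2, 4, "-") == "ACG"

    def test_unknown_chromosome(self):
        asm = GenomeAssembly("t", {"chr1": "ACGTA"})
        with pytest.raises(UnknownChromosomeError):
            get_genomic_sequence(asm, "chrX", 1, 1)

    def test_out_of_range(self):
        asm = GenomeAssembly("t", {"chr1": "ACGTA"})
        with pytest.raises(CoordinateError):
            get_genomic_sequence(asm, "chr1", 4, 9)

    def test_matches_bruteforce_extraction(self, toy):
        rng = random.Random(42)
        for chrom, seq in toy.assembly.sequences.items():
            for _ in range(50):
                s = rng.randint(1, len(seq))
                e = rng.randint(s, len(seq))
                plus = get_genomic_sequence(toy.assembly, chrom, s, e, "+")
                assert plus == "".join(seq[i - 1] for i in range(s, e + 1))
                assert get_genomic_sequence(
                    toy.assembly, chrom, s, e, "-"
                ) == reverse_complement(plus)

    @pytest.mark.parametrize("seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT")])
    def test_revcomp_hand_checked(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_revcomp_rejects_bad_alphabet(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ACGU")


class TestProteinSequence:
    def test_minimal_cds(self):
        asm = GenomeAssembly("t", {"chr1": "TT" + "ATGAAATAA" + "TT"})
        t = _tx(exons=[(3, 11)], cds_start_g=3, cds_end_g=11)
        assert get_protein_sequence(t, asm) == "MK"

    def test_premature_stop_names_residue(self):
        asm = GenomeAssembly("t", {"chr1": "ATGTAAAAATAA"})
        t = _tx(exons=[(1, 12)], cds_start_g=1, cds_end_g=12)
        with pytest.raises(TranslationError, match="residue 2"):
            get_protein_sequence(t, asm)

    def test_agrees_with_independent_oracle(self, toy):
        for t in toy.transcripts:
            assert get_protein_sequence(t, toy.assembly) == oracle_translate(
                t, toy.assembly
            )


class TestTranscriptValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            _tx(exons=[(11, 19), (15, 30)], cds_end_g=18)

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            _tx(exons=[(11, 20)], cds_start_g=11, cds_end_g=20)

    def test_cds_bound_outside_exon_rejected(self):
        with pytest.raises(ValidationError, match="not inside an exon"):
            _tx(exons=[(11, 19)], cds_start_g=5, cds_end_g=13)


class TestSelectTranscript:
    def test_mane_flag_honored(self):
        txs = [
            _tx(transcript_id="A", exons=[(1, 9)], cds_start_g=1, cds_end_g=9),
            _tx(
                transcript_id="B",
                exons=[(1, 9)],
                cds_start_g=1,
                cds_end_g=9,
                is_mane=True,
            ),
        ]
        choice = select_transcript("G1", txs)
        assert choice.transcript.transcript_id == "B"
        assert choice.rule == "mane"

    def test_longest_cds_fallback(self):
        txs = [
            _tx(transcript_id="A", exons=[(1, 300)], cds_start_g=1, cds_end_g=300),
            _tx(transcript_id="B", exons=[(1, 303)], cds_start_g=1, cds_end_g=303),
        ]
        choice = select_transcript("G1", txs)
        assert choice.transcript.transcript_id == "B"
        assert choice.rule == "longest-cds"

    def test_tie_breaks_to_smaller_id(self):
        txs = [
            _tx(transcript_id="Z9", exons=[(1, 300)], cds_start_g=1, cds_end_g=300),
            _tx(transcript_id="A1", exons=[(1, 300)], cds_start_g=1, cds_end_g=300),
        ]
        assert select_transcript("G1", txs).transcript.transcript_id == "A1"

    def test_unknown_gene(self, toy):
        with pytest.raises(UnknownGeneError):
            select_transcript("NOPE", toy.transcripts)


class TestAnnotationLoading:
    def test_tsv_gff3_cross_format_equivalence(self, toy, tmp_path):
        ref = make_toy_reference(seed=5, outdir=str(tmp_path))
        via_tsv = load_transcripts(str(tmp_path / "transcripts.tsv"), "tsv")
        via_gff = load_transcripts(str(tmp_path / "transcripts.gff3"), "gff3")
        by_id = {t.transcript_id: t for t in via_gff}
        assert len(via_tsv) == len(via_gff) == len(ref.transcripts)
        for t in via_tsv:
            g = by_id[t.transcript_id]
            assert (t.exons, t.cds_start_g, t.cds_end_g, t.strand, t.is_mane) == (
                g.exons,
                g.cds_start_g,
                g.cds_end_g,
                g.strand,
                g.is_mane,
            )
            assert t.gene_symbol == g.gene_symbol

    def test_bad_cds_length_in_tsv_names_transcript(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_transcripts_tsv([], str(path))
        path.write_text(
            path.read_text()
            + "BADTX\tG\ttoy\tchr1\t+\t1\t10\t1\t10\t1\n"
        )
        with pytest.raises(ValidationError, match="BADTX"):
            load_transcripts(str(path), "tsv")

    def test_symbol_table_round_trip(self, tmp_path):
        p = tmp_path / "sym.tsv"
        p.write_text(
            "approved_symbol\talias_symbols\tprevious_symbols\n"
            "MET\tHGFR|AUTS9\t\n"
            "BRAF\t\tBRAF1\n"
        )
        table = load_gene_symbols(str(p))
        assert table.lookup_approved("met") == "MET"
        assert table.lookup_alias("HGFR") == ["MET"]
        assert table.lookup_previous("braf1") == ["BRAF"]
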