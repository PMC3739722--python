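"""Swiss-Prot parsing, tokenization, keyword filtering, alignments."""

import io

import pytest

from mutmapper.records import (
    Alignment,
    AlignmentError,
    Expression,
    RecordError,
    emit_pubmed_query,
    filter_keywords,
    load_user_expressions,
    parse_fasta_alignment,
    parse_uniprot_records,
    read_expression_file,
    significant_token,
    tokenize_expression,
    write_expression_file,
)

from conftest import LEGACY_FLATFILE, PTEN_LIKE_FLATFILE, make_record


class TestFlatFileParsing:
    def test_modern_record_names_and_synonyms(self, pten_record):
        texts = {e.text for e in pten_record.expressions}
        assert {
            "Phosphatase and tensin homolog",
            "PTEN",
            "Mutated in multiple advanced cancers 1",
            "MMAC1",
            "TEP1",
        } <= texts
        sources = {e.source for e in pten_record.expressions}
        assert {"recommended_name", "gene_name", "synonym"} <= sources
        assert pten_record.entry_id == "PTEN_TEST"
        assert pten_record.accessions == ["P60484", "O00633"]

    def test_feature_variants_transcribed(self, pten_record):
        variants = {(f.position, f.wild, f.mutant, f.category)
                    for f in pten_record.feature_variants}
        assert variants == {
            (13, "A", "G", "natural_variant"),
            (3, "T", "D", "mutagenesis"),
        }

    def test_legacy_dialect_tolerated(self):
        rec = parse_uniprot_records(LEGACY_FLATFILE)[0]
        assert rec.entry_id == "CHEY_TEST"
        assert {e.text for e in rec.expressions} == {
            "Chemotaxis protein CheY",
            "CHEY",
        }
        assert {(f.position, f.wild, f.mutant) for f in rec.feature_variants} == {
            (2, "K", "R"),
            (4, "A", "G"),
        }

    def test_minimal_record_has_only_recommended_name(self):
        text = PTEN_LIKE_FLATFILE
        minimal = "\n".join(
            line for line in text.splitlines()
            if not line.startswith(("DE            Short", "DE   AltName", "GN", "FT"))
        ) + "\n"
        rec = parse_uniprot_records(minimal)[0]
        assert [e.text for e in rec.expressions] == ["Phosphatase and tensin homolog"]

    def test_unknown_residue_letter_names_entry(self):
        bad = PTEN_LIKE_FLATFILE.replace(
            "MKTAYIAKQR KSAWLDNMVE", "MKTAYIAKQR KSXWLDNMVE"
        )
        with pytest.raises(RecordError, match="PTEN_TEST"):
            parse_uniprot_records(bad)

    def test_feature_wild_mismatch_names_entry(self):
        bad = PTEN_LIKE_FLATFILE.replace('/note="A -> G', '/note="W -> G')
        with pytest.raises(RecordError, match="PTEN_TEST"):
            parse_uniprot_records(bad)

    def test_malformed_record_raises(self):
        with pytest.raises(RecordError):
            parse_uniprot_records("AC   P00001;\n//\n")


class TestTokenization:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (
                "Glutamate receptor, ionotropic kainate 5",
                ["GLUTAMATE", "RECEPTOR", "IONOTROPIC", "KAINATE", "5"],
            ),
            ("GLYCOPHORIN-A", ["GLYCOPHORIN", "A"]),
            ("NR1", ["NR1"]),
            ("  spaced   out  ", ["SPACED", "OUT"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize_expression(text) == expected

    def test_whitespace_only_yields_empty(self):
        assert tokenize_expression("  , - ") == []


class TestKeywordFilter:
    @pytest.mark.parametrize(
        "token,kept",
        [
            ("M", False),       # one-letter gene names flood retrieval
            ("AB", False),
            ("NR1", True),      # three characters containing a digit
            ("GPA", False),     # three letters, no digit
            ("GYPA", True),
        ],
    )
    def test_significance_rule(self, token, kept):
        assert significant_token(token) is kept

    def test_exempt_tokens_bypass_filter(self):
        assert significant_token("GPA", exempt_tokens=frozenset({"GPA"}))

    def test_dropped_expression_contributes_nothing(self):
        exprs = [Expression.from_text("M", "gene_name")]
        assert filter_keywords(exprs) == []

    def test_multi_token_expression_becomes_phrase(self):
        exprs = [
            Expression.from_text("Chemotaxis protein CheY", "recommended_name"),
            Expression.from_text("CheY", "gene_name"),
        ]
        assert filter_keywords(exprs) == ["CHEMOTAXIS PROTEIN CHEY", "CHEY"]

    def test_idempotent_and_order_preserving(self, pten_record):
        keywords = filter_keywords(pten_record.expressions)
        again = filter_keywords(
            [Expression.from_text(k, "user") for k in keywords]
        )
        assert again == keywords
        for keyword in keywords:
            for token in keyword.split():
                assert len(token) >= 3
                assert len(token) > 3 or any(c.isdigit() for c in token)

    def test_query_is_or_disjunction_of_quoted_phrases(self):
        assert emit_pubmed_query(["CHEY"]) == '"CHEY"'
        assert emit_pubmed_query(["PTEN", "MMAC1"]) == '"PTEN" OR "MMAC1"'
        exprs = [
            Expression.from_text("Chemotaxis protein CheY", "recommended_name"),
            Expression.from_text("CheY", "gene_name"),
        ]
        query = emit_pubmed_query(filter_keywords(exprs))
        assert query == '"CHEMOTAXIS PROTEIN CHEY" OR "CHEY"'

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError):
            emit_pubmed_query([])


class TestAlignmentParsing:
    def test_single_sequence_with_gap(self):
        rec = make_record("PROTA_TEST", "P00001", "Protein A", "MKTA")
        aln = parse_fasta_alignment(">P00001\nMK-TA\n", [rec])
        assert aln.columns == 5
        assert len(aln.rows) == 1

    def test_ragged_rows_rejected(self, alpha_beta_records):
        fasta = ">P00001\nMKTAYIAKQR\n>P00002\nMKTGYIAKQR--\n"
        with pytest.raises(AlignmentError, match="ragged"):
            parse_fasta_alignment(fasta, alpha_beta_records)

    @pytest.mark.parametrize(
        "header",
        ["P00001", "ALPHA_TEST", "sp|P00001|ALPHA_TEST", "tr|P00001|whatever"],
    )
    def test_header_dialects_resolve(self, header, alpha_beta_records):
        aln = parse_fasta_alignment(f">{header}\nMKTAYIAKQR\n", alpha_beta_records)
        assert aln.rows[0][0].entry_id == "ALPHA_TEST"

    def test_unresolvable_header_named_in_error(self, alpha_beta_records):
        with pytest.raises(AlignmentError, match="NOSUCH"):
            parse_fasta_alignment(">NOSUCH\nMKTAYIAKQR\n", alpha_beta_records)

    def test_degap_mismatch_names_record(self, alpha_beta_records):
        with pytest.raises(AlignmentError, match="ALPHA_TEST"):
            parse_fasta_alignment(">P00001\nMKTAYIAKQW\n", alpha_beta_records)

    def test_degapping_rows_reproduces_sequences(self, alpha_beta_records):
        fasta = ">P00001\nMKTA--YIAKQR\n>P00002\nMKTG.YIAKQR-\n"
        aln = parse_fasta_alignment(fasta, alpha_beta_records)
        for rec, gapped in aln.rows:
            assert gapped.replace("-", "").replace(".", "") == rec.sequence


class TestExpressionFiles:
    def test_user_expression_appended(self, alpha_beta_records):
        load_user_expressions("ALPHA_TEST\tNR1\n", alpha_beta_records)
        alpha = alpha_beta_records[0]
        assert alpha.expressions[-1].text == "NR1"
        assert alpha.expressions[-1].source == "user"

    def test_accession_also_resolves(self, alpha_beta_records):
        load_user_expressions("P00002\tBetaX\n", alpha_beta_records)
        assert alpha_beta_records[1].expressions[-1].text == "BetaX"

    def test_empty_file_changes_nothing(self, alpha_beta_records):
        before = [list(r.expressions) for r in alpha_beta_records]
        load_user_expressions("", alpha_beta_records)
        assert [list(r.expressions) for r in alpha_beta_records] == before

    def test_unknown_identifier_names_line(self, alpha_beta_records):
        with pytest.raises(ValueError, match="line 2"):
            load_user_expressions(
                "ALPHA_TEST\tok\nNOSUCH_ID\tnope\n", alpha_beta_records
            )

    def test_round_trip(self, alpha_beta_records):
        load_user_expressions("ALPHA_TEST\tNR1\n", alpha_beta_records)
        buffer = io.StringIO()
        write_expression_file(alpha_beta_records, buffer)
        before = [list(r.expressions) for r in alpha_beta_records]
        read_expression_file(buffer.getvalue(), alpha_beta_records)
        assert [list(r.expressions) for r in alpha_beta_records] == before


def test_alignment_rows_must_match_record(alpha_beta_records):
    with pytest.raises(AlignmentError):
        Alignment(rows=[(alpha_beta_records[0], "MKTAYIAKQW")], columns=10)
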