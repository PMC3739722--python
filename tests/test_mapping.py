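"""Expression matching, position validation, and the mapping algorithm."""

import pytest

from mutmapper.extraction import Document, MutationMention, extract_mentions
from mutmapper.mapping import (
    EngineConfig,
    MappingResult,
    map_corpus,
    map_document,
    map_mention,
    map_uniprot_features,
    match_expressions,
    validate_position,
)
from mutmapper.records import Expression, parse_uniprot_records

from conftest import PTEN_LIKE_FLATFILE, make_record


def doc(text, doc_id="D1"):
    return Document.from_text(doc_id, text)


def mention(wild, position, mutant, sentence_index=0, doc_id="D1"):
    return MutationMention(
        wild=wild,
        position=position,
        mutant=mutant,
        doc_id=doc_id,
        sentence_index=sentence_index,
        span=(0, 0),
        raw=f"{wild}{position}{mutant}",
    )


class TestExpressionMatching:
    @pytest.fixture
    def kainate_record(self):
        rec = make_record(
            "GRIK5_TEST", "Q63273", "Glutamate receptor, ionotropic kainate 5",
            "MKTAYIAKQR",
        )
        return rec

    def test_precision_needs_every_significant_word(self, kainate_record):
        sentence = "The glutamate receptor, ionotropic kainate 5 subunit was cloned."
        hits = match_expressions(doc(sentence), [kainate_record], "precision")
        assert len(hits) == 1
        assert hits[0].sentence_index == 0

    def test_partial_expression_precision_vs_recall(self, kainate_record):
        partial = doc("Binding of the kainate 5 subunit was unchanged by glutamate salts.")
        assert match_expressions(partial, [kainate_record], "precision") == []
        hits = match_expressions(partial, [kainate_record], "recall")
        assert len(hits) == 1
        assert set(hits[0].matched_words) == {"GLUTAMATE", "KAINATE"}

    def test_single_word_expression_hits_in_both_modes(self):
        rec = make_record("PTEN_TEST", "P60484", "PTEN", "MKTAYIAKQR")
        d = doc("PTEN is deleted in many tumours.")
        for mode in ("precision", "recall"):
            assert len(match_expressions(d, [rec], mode)) == 1

    def test_matching_is_whole_word(self):
        rec = make_record("PTEN_TEST", "P60484", "PTEN", "MKTAYIAKQR")
        assert match_expressions(doc("The PTENLIKE gene differs."), [rec], "recall") == []

    def test_precision_candidates_subset_of_recall(self, kainate_record):
        rec2 = make_record("OTHER_TEST", "P11111", "Ionotropic receptor beta", "MKTAYIAKQR")
        d = doc(
            "The glutamate receptor, ionotropic kainate 5 subunit was examined. "
            "An ionotropic current was recorded."
        )
        for records in ([kainate_record], [kainate_record, rec2]):
            precision = {h.record.entry_id for h in match_expressions(d, records, "precision")}
            recall = {h.record.entry_id for h in match_expressions(d, records, "recall")}
            assert precision <= recall


class TestValidatePosition:
    @pytest.mark.parametrize(
        "wild,position,expected",
        [
            ("K", 2, True),
            ("A", 2, False),   # residue 2 is K
            ("G", 536, False), # out of range
            ("M", 1, True),
            ("R", 10, True),
        ],
    )
    def test_examples(self, wild, position, expected, alpha_beta_records):
        alpha = alpha_beta_records[0]
        assert validate_position(alpha, mention(wild, position, "W")) is expected


class TestMapMention:
    def test_single_named_record_maps(self, alpha_beta_records):
        alpha = alpha_beta_records[0]
        d = doc("Protein alpha was purified. The K2R mutant lost activity.")
        res = map_mention(d, mention("K", 2, "R", sentence_index=1), [alpha])
        assert res.status == "mapped"
        assert res.matched_ids == ["ALPHA_TEST"]

    def test_window_empty_tie_stays_multi_mapped(self, alpha_beta_records):
        # both proteins named far from the mention; K2R validates on both
        d = doc(
            "Protein alpha was studied extensively. "
            "Protein beta was studied as a control. "
            "Some unrelated background is given here. "
            "Some more background follows now. "
            "The K2R mutant lost all activity."
        )
        res = map_mention(d, mention("K", 2, "R", sentence_index=4), alpha_beta_records)
        assert res.status == "multi_mapped"
        assert set(res.matched_ids) == {"ALPHA_TEST", "BETA_TEST"}

    def test_window_disambiguates_to_named_neighbour(self, alpha_beta_records):
        d = doc(
            "Protein beta was studied as a control. "
            "Some unrelated background is given here. "
            "Some more background follows now. "
            "Protein alpha carrying K2R lost all activity."
        )
        res = map_mention(d, mention("K", 2, "R", sentence_index=3), alpha_beta_records)
        assert res.status == "mapped"
        assert res.matched_ids == ["ALPHA_TEST"]

    def test_off_query_mutations_non_mapped(self):
        # mutations described on another protein fail to validate on the query
        pten = parse_uniprot_records(PTEN_LIKE_FLATFILE)[0]
        text = (
            "Six different beta-catenin mutations were found "
            "(G34E, G34V, S33C, D32Y, S33F, D32A). "
            "No mutations of the PTEN gene were identified."
        )
        results = map_document(doc(text), [pten])
        assert len(results) == 6
        assert {r.status for r in results} == {"non_mapped"}

    def test_window_enlargement_never_unmaps(self, alpha_beta_records):
        d = doc(
            "Protein alpha was studied extensively. "
            "Some unrelated background is given here. "
            "The K2R mutant lost all activity."
        )
        m = mention("K", 2, "R", sentence_index=2)
        for radius in range(0, 5):
            res = map_mention(
                d, m, alpha_beta_records, EngineConfig(window_radius=radius)
            )
            assert res.status != "non_mapped"

    def test_status_cardinality_enforced(self, alpha_beta_records):
        with pytest.raises(ValueError, match="inconsistent"):
            MappingResult(mention("K", 2, "R"), "mapped", [], "precision")

    def test_unsound_match_rejected(self, alpha_beta_records):
        alpha = alpha_beta_records[0]
        with pytest.raises(ValueError, match="unsound"):
            MappingResult(mention("A", 2, "K"), "mapped", [(alpha, 2)], "precision")


class TestMapCorpus:
    def test_empty_corpus(self, alpha_beta_records):
        assert map_corpus([], alpha_beta_records) == []

    def test_unique_validation_forces_zero_multi_mapped(self, alpha_beta_records):
        # A4G validates on alpha only, G4A on beta only (they differ at 4)
        docs = [
            doc("Protein alpha and Protein beta were compared. The A4G mutant failed.", "D1"),
            doc("Protein alpha and Protein beta were compared. The G4A mutant failed.", "D2"),
        ]
        results = map_corpus(docs, alpha_beta_records)
        assert [r.status for r in results] == ["mapped", "mapped"]
        assert [r.matched_ids for r in results] == [["ALPHA_TEST"], ["BETA_TEST"]]

    def test_deterministic_ordering(self, alpha_beta_records):
        docs = [
            doc("Protein alpha was used. K2R and T3W and M1W were made.", "D2"),
            doc("Protein alpha was used. K8R was made.", "D1"),
        ]
        results = map_corpus(docs, alpha_beta_records)
        keys = [(r.mention.doc_id, r.mention.position, r.mention.wnm) for r in results]
        assert keys == sorted(keys)


class TestUniprotFeatures:
    def test_each_feature_becomes_a_mapped_result(self):
        pten = parse_uniprot_records(PTEN_LIKE_FLATFILE)[0]
        results = map_uniprot_features([pten])
        assert len(results) == 2
        assert {r.status for r in results} == {"mapped"}
        assert {r.origin for r in results} == {"uniprot_annotation"}
        assert {(r.mention.wild, r.mention.position, r.mention.mutant)
                for r in results} == {("A", 13, "G"), ("T", 3, "D")}

    def test_record_without_features_yields_nothing(self, alpha_beta_records):
        assert map_uniprot_features(alpha_beta_records) == []
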