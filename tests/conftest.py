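import pytest

from mutmapper.records import Expression, ProteinRecord, parse_uniprot_records

# A modern-dialect Swiss-Prot entry styled after the human PTEN record:
# recommended + alternative names, gene name with synonyms, and both
# feature categories.
PTEN_LIKE_FLATFILE = """\
ID   PTEN_TEST               Reviewed;          40 AA.
AC   P60484; O00633;
DT   01-JAN-2000, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Phosphatase and tensin homolog;
DE            Short=PTEN;
DE   AltName: Full=Mutated in multiple advanced cancers 1;
GN   Name=PTEN; Synonyms=MMAC1, TEP1;
FT   VARIANT         13
FT                   /note="A -> G (in a tumour sample)"
FT   MUTAGEN         3
FT                   /note="T -> D: Loss of phosphatase activity."
SQ   SEQUENCE   40 AA;  4400 MW;  0000000000000000 CRC64;
     MKTAYIAKQR KSAWLDNMVE CRQPLHEFGI TVNDSWKYHC
//
"""

# The same entry rewritten in the legacy single-line dialect.
LEGACY_FLATFILE = """\
ID   CHEY_TEST      STANDARD;      PRT;   10 AA.
AC   P0AE67;
DT   01-JAN-1990 (Rel. 15, Created)
DE   Chemotaxis protein CheY.
GN   CHEY.
FT   VARIANT       2      2       K -> R (IN A MUTANT STRAIN).
FT   MUTAGEN       4      4       A->G: LOSS OF SWITCHING.
SQ   SEQUENCE   10 AA;  1100 MW;  00000000 CRC32;
     MKTAYIAKQR
//
"""


@pytest.fixture
def pten_record():
    return parse_uniprot_records(PTEN_LIKE_FLATFILE)[0]


def make_record(entry_id, accession, name, sequence, extra_names=()):
    exprs = [Expression.from_text(name, "recommended_name")]
    exprs += [Expression.from_text(t, "synonym") for t in extra_names]
    return ProteinRecord(
        entry_id=entry_id,
        accessions=[accession],
        expressions=exprs,
        sequence=sequence,
        feature_variants=[],
    )


@pytest.fixture
def alpha_beta_records():
    """Two records differing at position 4 only; K2R validates on both."""
    alpha = make_record("ALPHA_TEST", "P00001", "Protein alpha", "MKTAYIAKQR")
    beta = make_record("BETA_TEST", "P00002", "Protein beta", "MKTGYIAKQR")
    return [alpha, beta]
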