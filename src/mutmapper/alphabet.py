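"""Canonical amino-acid alphabets shared across the package."""

from Bio.Data.IUPACData import protein_letters, protein_letters_3to1

#: The 20 canonical one-letter residue codes.
CANONICAL_AA: frozenset[str] = frozenset(protein_letters)

#: Three-letter -> one-letter code table, canonical residues only
#: (extended codes such as Asx/Sec are deliberately excluded: a mention
#: whose residue falls outside the 20 canonical codes is discarded).
THREE_TO_ONE: dict[str, str] = {
    three: one
    for three, one in protein_letters_3to1.items()
    if one in CANONICAL_AA
}

ONE_TO_THREE: dict[str, str] = {one: three for three, one in THREE_TO_ONE.items()}
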