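# mutmapper

Map point-mutation mentions from biomedical abstracts onto protein
sequences and multiple sequence alignments.

## The problem

Site-directed mutagenesis and SNP studies fill the literature with
point-mutation statements such as "the K2R mutant lost activity", but
linking each mention to the correct protein — and to the equivalent
position in related proteins — is laborious and error-prone. The usual
text-mining direction (start from text, recognise entities) struggles
because protein naming is not standardised. `mutmapper` inverts the
workflow: it starts from the protein side. Query sequences (optionally
arranged as an MSA) are read from UniProtKB/Swiss-Prot records together
with every name, synonym and gene symbol by which the literature may
refer to them; abstracts are then mined for mutation mentions and each
mention is *validated against the sequences themselves*.

A mention is written in wNm form — wild-type residue `w`, 1-based
position `N`, mutant residue `m` (e.g. `A123G`). Mapping has three
outcomes:

* **mapped** — the abstract names exactly one query protein whose
  sequence carries residue `w` at position `N`;
* **non-mapped** — no named query protein validates the mention (gene
  mutations, cell-line tokens such as `T47D`, and mutations on other
  proteins end up here);
* **multi-mapped** — several named proteins validate it; a ±1-sentence
  window around the mention is used to disambiguate, and ties that
  survive the window stay multi-mapped.

Two expression-matching modes trade precision against recall: high
precision requires *all* of a name's significant words in a sentence,
high recall requires two or more. Results can be projected onto the
columns of an alignment, so mutations performed at equivalent positions
in related proteins line up, and scored against gold annotations with

    recall    = tp / (tp + fn)          precision = tp / (tp + fp)
    accuracy  = (tp + tn) / total       F         = 2·tp / (2·tp + fp + fn)

where a mention is tp when the mapped set contains its true protein, fp
when it does not, tn when a mention belonging to no query protein is
left unmapped, and fn when a real mutation is missed.

## Worked example

```python
from mutmapper import Document, EngineConfig, map_document, parse_uniprot_records

flatfile = """\
ID   PTEN_TEST               Reviewed;          40 AA.
AC   P60484;
DT   01-JAN-2000, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Phosphatase and tensin homolog;
DE            Short=PTEN;
GN   Name=PTEN; Synonyms=MMAC1, TEP1;
SQ   SEQUENCE   40 AA;  4400 MW;  0000000000000000 CRC64;
     MKTAYIAKQR KSAWLDNMVE CRQPLHEFGI TVNDSWKYHC
//
"""
records = parse_uniprot_records(flatfile)

abstract = (
    "Tumour suppression by PTEN requires its phosphatase activity. "
    "The K2R mutant abolished activity, and a point mutation in "
    "exon 5 (A536G) of another gene was also reported. "
    "Assays were carried out in T47D cells."
)
doc = Document.from_text("PMID0001", abstract)
for res in map_document(doc, records, EngineConfig(mode="precision")):
    print(res.mention.wnm, res.status, res.matched_ids)
```

prints

```
K2R mapped ['PTEN_TEST']
A536G non_mapped []
T47D non_mapped []
```

`K2R` validates on the query sequence (residue 2 is K) and the abstract
names PTEN, so it is mapped. `A536G` is a nucleotide change far beyond
the 40-residue sequence and `T47D` is a cell line; both are correctly
rejected as non-mapped — the extractor is deliberately permissive and
relies on sequence validation to trap such confounders.

## Command line

```sh
# generate a seeded synthetic fixture bundle (records, corpus, gold)
mutmapper synth --seed 11 --docs 20 --out bundle \
    --confounders gene=0.3,cell=0.2,off=0.2,trap=0.2

# run the pipeline and score it against the gold file
mutmapper run --records bundle/records.dat --msa bundle/alignment.fasta \
    --abstracts bundle/corpus --mode precision --gold bundle/gold.tsv --out out
```

`run` writes `mappings.tsv`/`mappings.json`, the effective expression
file, an annotated plain-text alignment, a self-contained HTML report,
a per-column TSV, and (with `--gold`) `evaluation.tsv`/`evaluation.json`.

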