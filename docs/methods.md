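# Methods

## Pipeline

`mutmapper` grounds point-mutation mentions in protein sequences rather
than recognising proteins from free text alone. The stages are:

1. **Record parsing** (`mutmapper.records`). UniProtKB/Swiss-Prot
   flat-file entries are parsed with Biopython's Swiss-Prot reader after
   a small normalising pre-pass that rewrites legacy-dialect `GN` lines
   and single-line `FT` features into the current dialect, so fixtures
   from either era parse identically. Every DE RecName/AltName Full and
   Short name and every GN Name/Synonym becomes a name *expression*;
   `FT VARIANT` and `FT MUTAGEN` features with a single-residue
   `X -> Y` note become feature variants (their wild-type letter is
   checked against the sequence at parse time; anything else in the
   note — deletions, ranges, "Missing" — is skipped). Sequences must be
   over the 20 canonical one-letter codes; isoform or mature-peptide
   numbering offsets are *not* corrected — positions are always
   canonical-sequence 1-based.

2. **Mention extraction** (`mutmapper.extraction`). Abstracts are split
   into sentences (split after `.!?` + whitespace + uppercase/digit,
   with a fixed, versioned guard list for abbreviations and single
   initials; a period with no following whitespace never splits, which
   protects tokens like `p.A123G`). Three regex families are matched at
   word-ish boundaries (start/end of text or any non-alphanumeric
   character, so `Y1472F-KI` matches): compact one-letter `W123M`,
   three-letter `Trp123Met` (case-insensitive), and arrow/"to" forms
   (`W123 -> M`, `Trp123 to Met`). All matches normalise to uppercase
   wNm; a match whose residue falls outside the canonical 20 (`V125X`)
   or whose wild and mutant coincide is dropped. Extraction is
   deliberately permissive: cell-line tokens (`T47D`) and
   nucleotide-level changes are extracted and left to the mapping stage,
   which rejects them by sequence validation. Mentions are deduplicated
   to one representative per (document, wNm) key, keeping the first
   occurrence and retaining later spans as secondary evidence.

3. **Mapping** (`mutmapper.mapping`). For each document, expressions
   are searched sentence-by-sentence as case-insensitive whole-word
   bags (word order and adjacency are ignored). In *precision* mode a
   sentence must contain **all** of an expression's significant words;
   in *recall* mode two or more suffice; single-word expressions
   require that word in both modes, which makes the precision-mode
   candidate set a subset of the recall-mode set. The candidate set for
   a mention is every record named anywhere in the abstract whose
   sequence carries the wild-type residue at the stated position. One
   candidate → mapped; none → non-mapped; several → only candidates
   named within `window_radius` (default 1) sentences of the mention
   are kept, and if exactly one survives the mention is mapped,
   otherwise it is multi-mapped. When the window names *no* candidate,
   the abstract-level candidate set is retained as multi-mapped rather
   than discarded: those candidates did validate and were named, and
   dropping them would silently lose recall. The title is sentence 0;
   several synonyms of one record count once toward candidacy.
   Feature-table variants are overlaid as already-mapped results with
   origin `uniprot_annotation`.

4. **Alignment overlay** (`mutmapper.overlay`). Residue positions are
   translated to alignment columns (mutually inverse maps on non-gap
   cells; gap characters `-` and `.`). Aggregation is per column, not
   per residue identity, so different amino acids in one column are
   co-reported — the point of the overlay is equivalent *positions*.
   Each (result, matched record) pair contributes exactly one column
   entry. Reports (plain text, self-contained static HTML, TSV) are
   pure functions of their inputs.

5. **Evaluation** (`mutmapper.evaluation`). Per deduplicated mention:
   mapped/multi-mapped with the true protein in the matched set → tp (a
   multi-mapped set containing the truth is scored correct);
   mapped/multi-mapped without it → fp; non-mapped with no true protein
   → tn; non-mapped despite one → fn. The four scores are percentages;
   the reporting helper *truncates* — accuracy, precision and recall to
   integer percent and the F-measure to one decimal — using exact
   rational arithmetic, so 242/246 prints as 98.3, never 98.4. A
   zero-denominator score yields an undefined marker (None) rather than
   a crash; all-zero counts are an error.

## Keyword filtering

Query keywords are built from expressions token-wise: tokens of one or
two characters are dropped, three-character tokens are kept only if
they contain a digit (`NR1` survives, `GPA` does not), longer tokens
are kept. An expression whose tokens are all dropped contributes no
keyword. The same significance rule gates tokens during expression
matching (toggleable in `EngineConfig`). Because curated gene symbols
occasionally violate the three-letter rule, a per-call
`exempt_tokens` list can whitelist specific tokens. The query builder
emits an OR-disjunction of quoted keywords suitable for an E-utilities
`term` parameter; no network call is made anywhere in the package.

## Synthetic corpora

`mutmapper.synth` generates the fixture corpora the test-suite and the
acceptance script run on. Records get random canonical-residue
sequences (default 3 records × 60 residues), multi-word names and
gene-style synonyms, and 1–2 feature variants; with pairwise identity 0
the sequences share no (position, residue) pair, so no mention can
validate on two records, while raising the identity knob provokes
multi-mapping. Records are serialised to Swiss-Prot flat-file text and
re-parsed, so the real parser is exercised on every generated fixture.

Each document plants 1–3 true mentions (position sampled from a query
record, wild type taken from the sequence, mutant different). The
protein is named in the mention's sentence with probability 0.7, in an
adjacent sentence with 0.2 and two-plus sentences away with 0.1,
exercising all three branches of the window logic. Confounders are
planted per document at configurable rates:

* *gene mutation* — wNm in an "exon" sentence at positions 500–999,
  beyond every query sequence, so it can never validate;
* *cell-line token* — `T47D`/`T98G`, skipped if it would coincidentally
  validate on a query record;
* *off-target protein* — a mutation attributed to a distractor protein,
  with a wild/position pair that validates on no query record;
* *coincidental trap* — a mutation attributed to a distractor but
  engineered to validate on a named query record: the only intended
  false-positive source.

All confounders are gold-annotated as belonging to no query protein;
distractor vocabulary is disjoint from every query-name token. The
ambiguity knob flags true mentions (via a dedicated RNG stream, so the
flag sets are nested as the knob rises and the multi-mapped count is
monotone by construction) to be planted at positions where two records
share a residue, with both records named in the sentence. Every
generator output is a pure function of the spec and seed.

What the generator does *not* emulate: real PubMed prose style,
natural-language mutation descriptions ("substitution of alanine for
glycine"), author-specific numbering schemes (mature-peptide offsets,
motif-relative shorthand), abbreviation-induced sentence-splitting
pathologies beyond the guard list, and naming variation beyond the
planted synonym sets. Perfect recovery on clean synthetic corpora
therefore demonstrates the correctness of the mapping algebra, not
real-literature recall.

## Problem sizes

The acceptance script uses 100-document corpora (≈200–350 mentions)
for the end-to-end runs, the full 380 ordered residue pairs × positions
1–200 for the extraction-recovery rate, and the three benchmark
corpora's published confusion counts (435, 920 and 1254 mentions) for
the score arithmetic; the test-suite's exhaustive extraction oracle
covers positions 1–999. These sizes keep the whole suite in the
seconds-to-a-minute range while leaving every code path exercised.

## Known limitations

* Mentions using motif-relative or receptor-family shorthand numbering
  are extracted but validate at the wrong position (or not at all);
  no offset correction is attempted.
* Insertions, deletions, nonsense mutations and HGVS nucleotide syntax
  are out of scope; `c.A536G`-style strings are extracted only when
  they look like wNm and are then rejected by validation.
* Expression matching is bag-of-words per sentence; it performs no
  coreference resolution, abbreviation expansion or learned NER.
* Gold annotation is assumed single-source; no inter-annotator
  tooling is provided.
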