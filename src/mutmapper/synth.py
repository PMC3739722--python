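"""Seeded synthetic fixture corpora: records, abstracts and gold truth.

The generator emulates the situations a mutation-mapping pipeline meets
in real abstracts: true protein-attributed point mutations, plus the
documented confounders — nucleotide/gene mutations described at the exon
or mRNA level, cell-line tokens shaped like mutations (``T47D``),
mutations reported on proteins outside the query set, and
"coincidental traps": mutations belonging to another protein that
nevertheless validate on a query sequence because the same residue
occupies that position.  Traps are the engineered false-positive source;
every other confounder is rejection-sampled so it can never validate on
a query record, keeping the gold annotation clean.

Every output is a pure function of the spec (including its seed).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .alphabet import CANONICAL_AA
from .evaluation import GoldAnnotation, write_gold
from .extraction import Document
from .records import ProteinRecord, parse_uniprot_records

_AA = sorted(CANONICAL_AA)

# name banks; distractor vocabulary is disjoint from every query-name token
_FAMILIES = (
    "kinase", "channel", "transporter", "receptor",
    "phosphatase", "esterase", "reductase", "ligase",
)
_GREEK = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "theta", "kappa")
_DISTRACTOR_NOUNS = ("ferredoxin", "claudin", "villin", "gelsolin", "profilin", "titin")
_CELL_LINE_TOKENS = ("T47D", "T98G")

_TITLES = (
    "Functional consequences of engineered substitutions.",
    "Probing residue contributions by site-directed mutagenesis.",
    "Structure-function relationships explored through targeted substitutions.",
)
_FILLERS = (
    "The measurements were repeated in triplicate.",
    "Control experiments gave consistent results.",
    "Further biochemical characterization will be required.",
    "Binding assays were carried out at room temperature.",
    "The purified material remained stable for several weeks.",
)


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    ``confounder_rates`` are per-document probabilities of planting each
    confounder type; ``ambiguity`` is the probability that a planted true
    mutation sits at a position carrying the same residue in at least two
    query records (and names both, provoking multi-mapping).
    """

    seed: int
    n_docs: int
    records: list[ProteinRecord] | None = None
    n_records: int = 3
    seq_length: int = 60
    identity: float = 0.0
    true_mentions_per_doc: tuple[int, int] = (1, 3)
    confounder_rates: dict[str, float] = field(
        default_factory=lambda: {
            "gene_mutation": 0.4,
            "cell_line_token": 0.2,
            "off_target_protein": 0.2,
            "coincidental_trap": 0.0,
        }
    )
    ambiguity: float = 0.0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not 10 <= self.seq_length < 500:
            # gene-level confounders use positions 500-999 to guarantee
            # they fall outside every query sequence
            raise ValueError("seq_length must be in [10, 500)")
        for name, p in {**self.confounder_rates, "ambiguity": self.ambiguity}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {name} must be a probability, got {p}")


# ---------------------------------------------------------------------------
# record generation
# ---------------------------------------------------------------------------

def generate_records(
    seed: int, n: int, length: int = 60, identity: float = 0.0
) -> list[ProteinRecord]:
    """Random query records, serialized through the real flat-file parser.

    With ``identity`` = 0 the sequences share no (position, residue)
    pair, so no mutation can validate on two records; raising it copies
    residues from the first sequence with that probability, provoking
    multi-mapping downstream.
    """
    if not 1 <= n <= 12:
        raise ValueError("n must be in 1..12")
    rng = random.Random(seed)
    sequences: list[str] = []
    for i in range(n):
        seq = []
        for pos in range(length):
            if i > 0 and rng.random() < identity:
                seq.append(sequences[0][pos])
            elif identity == 0.0:
                used = {s[pos] for s in sequences}
                seq.append(rng.choice([a for a in _AA if a not in used]))
            else:
                seq.append(rng.choice(_AA))
        sequences.append("".join(seq))

    chunks = []
    for i, seq in enumerate(sequences):
        family = _FAMILIES[i % len(_FAMILIES)]
        greek = _GREEK[(i // len(_FAMILIES) + i) % len(_GREEK)]
        name = f"Synthetic {family} {greek}"
        gene = f"S{family[0].upper()}{greek[0].upper()}{i + 1}"
        entry = f"{gene}_SYNTH"
        accession = f"P{77000 + i}"
        n_feat = rng.randint(1, 2)
        ft_lines = []
        for k in range(n_feat):
            pos = rng.randint(1, length)
            wild = seq[pos - 1]
            mutant = rng.choice([a for a in _AA if a != wild])
            key = "VARIANT" if k % 2 == 0 else "MUTAGEN"
            ft_lines.append(f"FT   {key:<16}{pos}")
            ft_lines.append(
                f'FT                   /note="{wild} -> {mutant} (synthetic feature)"'
            )
        seq_lines = [
            "     " + " ".join(seq[j:j + 10] for j in range(k2, min(k2 + 60, length), 10))
            for k2 in range(0, length, 60)
        ]
        chunks.append(
            "\n".join(
                [
                    f"ID   {entry:<24}Reviewed;{length:>12} AA.",
                    f"AC   {accession};",
                    "DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.",
                    f"DE   RecName: Full={name};",
                    f"GN   Name={gene};",
                    *ft_lines,
                    f"SQ   SEQUENCE{length:>7} AA;{length * 110:>7} MW;  "
                    "0000000000000000 CRC64;",
                    *seq_lines,
                    "//",
                ]
            )
        )
    return parse_uniprot_records("\n".join(chunks) + "\n")


def records_to_flatfile(records: list[ProteinRecord]) -> str:
    """Serialize records back to Swiss-Prot flat-file text (current dialect)."""
    chunks = []
    for rec in records:
        lines = [
            f"ID   {rec.entry_id:<24}Reviewed;{len(rec.sequence):>12} AA.",
            "AC   " + "; ".join(rec.accessions) + ";",
            "DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.",
        ]
        gene_names = [e.text for e in rec.expressions if e.source == "gene_name"]
        synonyms = [e.text for e in rec.expressions if e.source == "synonym"]
        for expr in rec.expressions:
            if expr.source == "recommended_name":
                lines.append(f"DE   RecName: Full={expr.text};")
            elif expr.source == "alternative_name":
                lines.append(f"DE   AltName: Full={expr.text};")
        for gname in gene_names:
            gn = f"GN   Name={gname};"
            if synonyms:
                gn += " Synonyms=" + ", ".join(synonyms) + ";"
            lines.append(gn)
        key_of = {"natural_variant": "VARIANT", "mutagenesis": "MUTAGEN"}
        for fv in rec.feature_variants:
            lines.append(f"FT   {key_of[fv.category]:<16}{fv.position}")
            note = fv.description or f"{fv.wild} -> {fv.mutant}"
            lines.append(f'FT                   /note="{note}"')
        length = len(rec.sequence)
        lines.append(
            f"SQ   SEQUENCE{length:>7} AA;{length * 110:>7} MW;  "
            "0000000000000000 CRC64;"
        )
        for k in range(0, length, 60):
            block = rec.sequence[k:k + 60]
            lines.append(
                "     " + " ".join(block[j:j + 10] for j in range(0, len(block), 10))
            )
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _recommended_name(rec: ProteinRecord) -> str:
    for expr in rec.expressions:
        if expr.source == "recommended_name":
            return expr.text
    return rec.expressions[0].text


def _unique_positions(records: list[ProteinRecord], index: int) -> list[int]:
    """Positions where this record's residue differs from every other record's."""
    rec = records[index]
    out = []
    for pos in range(1, len(rec.sequence) + 1):
        residue = rec.sequence[pos - 1]
        clash = any(
            other is not rec
            and pos <= len(other.sequence)
            and other.sequence[pos - 1] == residue
            for other in records
        )
        if not clash:
            out.append(pos)
    return out


def _shared_positions(records: list[ProteinRecord]) -> list[tuple[int, int, int]]:
    """(record index, other index, position) triples with identical residues."""
    out = []
    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i == j:
                continue
            for pos in range(1, min(len(a.sequence), len(b.sequence)) + 1):
                if a.sequence[pos - 1] == b.sequence[pos - 1]:
                    out.append((i, j, pos))
    return out


def _pick_mutant(rng: random.Random, wild: str) -> str:
    return rng.choice([a for a in _AA if a != wild])


def _validates_anywhere(records: list[ProteinRecord], wild: str, pos: int) -> bool:
    return any(
        pos <= len(r.sequence) and r.sequence[pos - 1] == wild for r in records
    )


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], list[GoldAnnotation]]:
    """Generate documents and the complete gold truth for every planted mention.

    The protein is named in the mention's own sentence with probability
    0.7, in an adjacent sentence with 0.2, and two or more sentences away
    with 0.1, exercising all three branches of the sentence-window logic.
    """
    records = spec.records if spec.records is not None else generate_records(
        spec.seed, spec.n_records, spec.seq_length, spec.identity
    )
    if not records:
        raise ValueError("corpus spec has no records")
    query_tokens = {w for r in records for e in r.expressions for w in e.words}
    distractors = []
    for j, noun in enumerate(_DISTRACTOR_NOUNS):
        tail = f"{noun[:3].upper()}{90 + j}"
        assert noun.upper() not in query_tokens and tail not in query_tokens
        distractors.append((f"{noun} {tail}", tail))

    unique_pos = [_unique_positions(records, i) for i in range(len(records))]
    shared_pos = _shared_positions(records)
    docs: list[Document] = []
    gold: list[GoldAnnotation] = []

    for d in range(spec.n_docs):
        doc_rng = random.Random(spec.seed * 1_000_003 + d)
        # ambiguity decisions come from a dedicated stream so that raising
        # the knob only ever adds ambiguous plants (monotone by coupling)
        amb_rng = random.Random(spec.seed * 7919 + 104_729 * d)
        doc_id = f"SYN{d:05d}"
        sentences: list[str] = [doc_rng.choice(_TITLES)]
        used_keys: set[str] = set()
        named: set[int] = set()

        def plant_key(wild: str, pos: int, mutant: str) -> str | None:
            key = f"{wild}{pos}{mutant}"
            if key in used_keys:
                return None
            used_keys.add(key)
            return key

        n_true = doc_rng.randint(*spec.true_mentions_per_doc)
        for _ in range(n_true):
            ambiguous = amb_rng.random() < spec.ambiguity and bool(shared_pos)
            key = None
            if ambiguous:
                for _try in range(20):
                    i, j, pos = doc_rng.choice(shared_pos)
                    rec = records[i]
                    wild = rec.sequence[pos - 1]
                    key = plant_key(wild, pos, _pick_mutant(doc_rng, wild))
                    if key:
                        other = records[j]
                        sentences.append(
                            f"In {_recommended_name(rec)} and "
                            f"{_recommended_name(other)}, the {key} substitution "
                            "altered function."
                        )
                        named.update({i, j})
                        break
            else:
                for _try in range(20):
                    i = doc_rng.randrange(len(records))
                    rec = records[i]
                    pool = unique_pos[i] or list(range(1, len(rec.sequence) + 1))
                    pos = doc_rng.choice(pool)
                    wild = rec.sequence[pos - 1]
                    key = plant_key(wild, pos, _pick_mutant(doc_rng, wild))
                    if key:
                        break
                if key:
                    placement = doc_rng.random()
                    name = _recommended_name(rec)
                    if placement < 0.7:
                        sentences.append(
                            f"The {key} mutant of {name} showed reduced activity."
                        )
                    elif placement < 0.9:
                        sentences.append(f"These experiments used purified {name}.")
                        sentences.append(f"The {key} mutant showed reduced activity.")
                    else:
                        sentences.append(f"These experiments used purified {name}.")
                        sentences.append(doc_rng.choice(_FILLERS))
                        sentences.append(doc_rng.choice(_FILLERS))
                        sentences.append(f"The {key} mutant showed reduced activity.")
                    named.add(i)
            if key:
                gold.append(GoldAnnotation(doc_id, key, records[i].entry_id, "true"))

        rates = spec.confounder_rates
        if doc_rng.random() < rates.get("gene_mutation", 0.0):
            pos = doc_rng.randint(500, 999)  # beyond every query sequence
            wild = doc_rng.choice(_AA)
            key = plant_key(wild, pos, _pick_mutant(doc_rng, wild))
            if key:
                _, gene_tail = doc_rng.choice(distractors)
                sentences.append(
                    f"Sequencing revealed a point mutation in exon 5 ({key}) "
                    f"of the {gene_tail} gene."
                )
                gold.append(GoldAnnotation(doc_id, key, None, "gene_mutation"))

        if doc_rng.random() < rates.get("cell_line_token", 0.0):
            for token in doc_rng.sample(_CELL_LINE_TOKENS, len(_CELL_LINE_TOKENS)):
                wild, pos, mutant = token[0], int(token[1:-1]), token[-1]
                if _validates_anywhere(records, wild, pos):
                    continue  # would not be a clean true negative
                if plant_key(wild, pos, mutant):
                    sentences.append(f"All assays were performed in {token} cells.")
                    gold.append(GoldAnnotation(doc_id, token, None, "cell_line_token"))
                break

        if doc_rng.random() < rates.get("off_target_protein", 0.0):
            for _try in range(50):
                pos = doc_rng.randint(1, spec.seq_length)
                taken = {
                    r.sequence[pos - 1] for r in records if pos <= len(r.sequence)
                }
                free = [a for a in _AA if a not in taken]
                if not free:
                    continue
                wild = doc_rng.choice(free)
                key = plant_key(wild, pos, _pick_mutant(doc_rng, wild))
                if key:
                    dname, _ = doc_rng.choice(distractors)
                    sentences.append(
                        f"The {key} mutation in {dname} impaired folding."
                    )
                    gold.append(GoldAnnotation(doc_id, key, None, "off_target_protein"))
                    break

        if doc_rng.random() < rates.get("coincidental_trap", 0.0):
            for _try in range(20):
                i = doc_rng.randrange(len(records))
                rec = records[i]
                pos = doc_rng.randint(1, len(rec.sequence))
                wild = rec.sequence[pos - 1]
                key = plant_key(wild, pos, _pick_mutant(doc_rng, wild))
                if key:
                    if i not in named:
                        sentences.append(
                            "These findings extend earlier work on "
                            f"{_recommended_name(rec)}."
                        )
                        named.add(i)
                    dname, _ = doc_rng.choice(distractors)
                    sentences.append(
                        f"A {key} substitution in {dname} was described previously."
                    )
                    gold.append(GoldAnnotation(doc_id, key, None, "trap"))
                    break

        if doc_rng.random() < 0.5:
            sentences.append(doc_rng.choice(_FILLERS))
        docs.append(Document.from_text(doc_id, " ".join(sentences)))
    return docs, gold


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(spec: CorpusSpec, outdir: str | Path) -> dict[str, Path]:
    """Write records.dat, alignment.fasta, corpus/, gold.tsv and spec.json.

    The bundle is the input contract of the command-line pipeline; the
    same spec always produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = spec.records if spec.records is not None else generate_records(
        spec.seed, spec.n_records, spec.seq_length, spec.identity
    )
    docs, gold = generate_corpus(
        CorpusSpec(
            seed=spec.seed,
            n_docs=spec.n_docs,
            records=records,
            n_records=spec.n_records,
            seq_length=spec.seq_length,
            identity=spec.identity,
            true_mentions_per_doc=spec.true_mentions_per_doc,
            confounder_rates=spec.confounder_rates,
            ambiguity=spec.ambiguity,
        )
    )
    paths = {
        "records": outdir / "records.dat",
        "alignment": outdir / "alignment.fasta",
        "corpus": outdir / "corpus",
        "gold": outdir / "gold.tsv",
        "spec": outdir / "spec.json",
    }
    paths["records"].write_text(records_to_flatfile(records))
    width = max(len(r.sequence) for r in records)
    fasta = "".join(
        f">{r.entry_id}\n{r.sequence + '-' * (width - len(r.sequence))}\n"
        for r in records
    )
    paths["alignment"].write_text(fasta)
    paths["corpus"].mkdir(exist_ok=True)
    for doc in docs:
        (paths["corpus"] / f"{doc.doc_id}.txt").write_text(doc.text + "\n")
    with open(paths["gold"], "w") as fh:
        write_gold(gold, fh)
    paths["spec"].write_text(
        json.dumps(
            {
                "seed": spec.seed,
                "n_docs": spec.n_docs,
                "n_records": spec.n_records,
                "seq_length": spec.seq_length,
                "identity": spec.identity,
                "true_mentions_per_doc": list(spec.true_mentions_per_doc),
                "confounder_rates": spec.confounder_rates,
                "ambiguity": spec.ambiguity,
            },
            indent=2,
        )
        + "\n"
    )
    return paths
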