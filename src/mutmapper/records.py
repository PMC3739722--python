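"""Protein records, name expressions, query keywords and alignments.

This module parses UniProtKB/Swiss-Prot flat-file entries into
:class:`ProteinRecord` objects carrying every name string (``Expression``)
by which the protein may be referred to in text, the canonical amino-acid
sequence, and the feature-table substitutions (natural variants and
mutagenesis experiments).  It also resolves FASTA single sequences or
multiple sequence alignments against those records, builds the filtered
keyword set used to construct literature queries, and round-trips the
user-editable expression file.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO, SwissProt

from .alphabet import CANONICAL_AA

GAP_CHARS = "-."

EXPRESSION_SOURCES = (
    "recommended_name",
    "alternative_name",
    "gene_name",
    "synonym",
    "user",
)


class RecordError(ValueError):
    """A Swiss-Prot entry could not be parsed or fails an invariant."""


class AlignmentError(ValueError):
    """A FASTA sequence/alignment is inconsistent with the protein records."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_TOKEN_SPLIT = re.compile(r"[^A-Za-z0-9]+")


def tokenize_expression(text: str) -> list[str]:
    """Deterministic tokenization of a protein name expression.

    Splits on every character that is not a letter or digit, uppercases,
    and drops empty tokens, so that e.g. ``"Glycophorin-A"`` becomes
    ``["GLYCOPHORIN", "A"]``.
    """
    return [t for t in _TOKEN_SPLIT.split(text.upper()) if t]


@dataclass(frozen=True)
class Expression:
    """One name string for a protein, with its deterministic token list."""

    text: str
    words: tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        if self.source not in EXPRESSION_SOURCES:
            raise ValueError(f"unknown expression source {self.source!r}")
        if not self.words:
            raise ValueError(f"expression {self.text!r} tokenizes to nothing")

    @classmethod
    def from_text(cls, text: str, source: str) -> "Expression":
        return cls(text=text, words=tuple(tokenize_expression(text)), source=source)


@dataclass(frozen=True)
class FeatureVariant:
    """A single-residue substitution annotated in the feature table."""

    position: int  # 1-based residue index on the canonical sequence
    wild: str
    mutant: str
    category: str  # natural_variant | mutagenesis
    description: str = ""


@dataclass
class ProteinRecord:
    """One Swiss-Prot entry: identifiers, name expressions, sequence, variants."""

    entry_id: str
    accessions: list[str]
    expressions: list[Expression]
    sequence: str
    feature_variants: list[FeatureVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entry_id or not self.accessions:
            raise RecordError("record needs an entry name and >=1 accession")
        if not self.sequence:
            raise RecordError(f"{self.entry_id}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise RecordError(
                f"{self.entry_id}: non-canonical residue letters {sorted(bad)}"
            )
        if not self.expressions:
            raise RecordError(f"{self.entry_id}: no name expressions")
        for fv in self.feature_variants:
            if not 1 <= fv.position <= len(self.sequence):
                raise RecordError(
                    f"{self.entry_id}: feature position {fv.position} outside sequence"
                )
            if self.sequence[fv.position - 1] != fv.wild:
                raise RecordError(
                    f"{self.entry_id}: feature at {fv.position} claims wild-type "
                    f"{fv.wild} but sequence has {self.sequence[fv.position - 1]}"
                )

    def identifiers(self) -> set[str]:
        return {self.entry_id, *self.accessions}


@dataclass
class Alignment:
    """Gapped, equal-length rows, each linked to its protein record."""

    rows: list[tuple[ProteinRecord, str]]
    columns: int

    def __post_init__(self) -> None:
        for rec, gapped in self.rows:
            if len(gapped) != self.columns:
                raise AlignmentError(
                    f"row {rec.entry_id} has {len(gapped)} columns, expected {self.columns}"
                )
            if degap(gapped) != rec.sequence:
                raise AlignmentError(
                    f"de-gapped row for {rec.entry_id} does not equal its sequence"
                )

    def row_for(self, record: ProteinRecord) -> str:
        for rec, gapped in self.rows:
            if rec is record or rec.entry_id == record.entry_id:
                return gapped
        raise AlignmentError(f"record {record.entry_id} not in alignment")


def degap(gapped: str) -> str:
    return "".join(c for c in gapped if c not in GAP_CHARS).upper()


# ---------------------------------------------------------------------------
# Swiss-Prot flat-file parsing
# ---------------------------------------------------------------------------

_LEGACY_FT = re.compile(r"^FT   (\w[\w-]*)\s+(\d+)\s+(\d+)\s+(\S.*)$")
_LEGACY_FT_CONT = re.compile(r"^FT\s{20,}(\S.*)$")


def _modernize_flatfile(text: str) -> str:
    """Rewrite legacy-dialect GN and FT lines into the current dialect.

    Bio.SwissProt targets the current flat-file format; old entries wrote
    ``GN   CHEY.`` and single-line features such as
    ``FT   VARIANT       2      2       K -> R (IN A TUMOR).``  Those are
    translated into ``GN   Name=...;`` and location + /note form so one
    parser handles both eras.
    """
    out: list[str] = []
    legacy_note_open = False
    for line in text.splitlines():
        if line.startswith("GN   ") and "=" not in line:
            names = [n for n in re.split(r"\s+AND\s+", line[5:].strip().rstrip(".")) if n]
            if names:
                gn = f"GN   Name={names[0]};"
                if len(names) > 1:
                    gn += " Synonyms=" + ", ".join(names[1:]) + ";"
                out.append(gn)
                legacy_note_open = False
                continue
        m = _LEGACY_FT.match(line)
        if m and not line[5:].lstrip().startswith("/"):
            key, start, end, desc = m.groups()
            loc = start if start == end else f"{start}..{end}"
            out.append(f"FT   {key:<16}{loc}")
            out.append(f'FT                   /note="{desc.rstrip(".")}"')
            legacy_note_open = True
            continue
        if legacy_note_open:
            cont = _LEGACY_FT_CONT.match(line)
            if cont and not cont.group(1).startswith("/"):
                prev = out[-1]
                out[-1] = prev[:-1] + " " + cont.group(1).rstrip(".") + '"'
                continue
        legacy_note_open = False
        out.append(line)
    return "\n".join(out) + "\n"


_DE_NAME = re.compile(r"(RecName|AltName|SubName):([^;]*(?:;\s*(?:Short|EC|INN)=[^;]*)*)")
_DE_FIELD = re.compile(r"(Full|Short)=([^;{]+)")
_FT_SUBST = re.compile(r"^\s*([A-Z])\s*->\s*([A-Z])(?:\s*[(:;,.].*)?$", re.DOTALL)


def _expressions_from_description(description: str) -> list[Expression]:
    exprs: list[Expression] = []
    if "Name:" not in description:
        # legacy free-text DE line: the whole description is the name
        text = description.rstrip(". ")
        if text:
            exprs.append(Expression.from_text(text, "recommended_name"))
        return exprs
    first_full = True
    for block in re.finditer(_DE_NAME, description):
        kind = block.group(1)
        for fm in re.finditer(_DE_FIELD, block.group(2)):
            text = fm.group(2).strip()
            if not text:
                continue
            if kind == "RecName" and fm.group(1) == "Full" and first_full:
                exprs.append(Expression.from_text(text, "recommended_name"))
                first_full = False
            else:
                exprs.append(Expression.from_text(text, "alternative_name"))
    return exprs


def _clean_gn(value: str) -> str:
    return re.sub(r"\s*\{[^}]*\}", "", value).strip()


_FT_CATEGORY = {"VARIANT": "natural_variant", "MUTAGEN": "mutagenesis"}


def parse_uniprot_records(stream: TextIO | str) -> list[ProteinRecord]:
    """Parse Swiss-Prot flat-file text into :class:`ProteinRecord` objects.

    DE RecName/AltName Full and Short names and GN Name/Synonyms all become
    expressions; FT VARIANT and FT MUTAGEN features whose note is a
    single-residue ``X -> Y`` substitution become :class:`FeatureVariant`
    entries (anything else — deletions, multi-residue notes, "Missing" —
    is skipped).
    """
    text = stream if isinstance(stream, str) else stream.read()
    handle = io.StringIO(_modernize_flatfile(text))
    records: list[ProteinRecord] = []
    try:
        parsed = list(SwissProt.parse(handle))
    except Exception as exc:  # malformed entry: surface with context
        raise RecordError(f"malformed Swiss-Prot input: {exc}") from exc
    for sp in parsed:
        exprs = _expressions_from_description(sp.description)
        for gene in sp.gene_name:
            name = _clean_gn(gene.get("Name", ""))
            if name:
                exprs.append(Expression.from_text(name, "gene_name"))
            for syn in gene.get("Synonyms", []):
                syn = _clean_gn(syn)
                if syn:
                    exprs.append(Expression.from_text(syn, "synonym"))
        variants: list[FeatureVariant] = []
        for feat in sp.features:
            category = _FT_CATEGORY.get(feat.type)
            if category is None:
                continue
            start = int(feat.location.start)  # 0-based, end-exclusive
            end = int(feat.location.end)
            if end - start != 1:
                continue
            note = feat.qualifiers.get("note", "")
            m = _FT_SUBST.match(note)
            if not m:
                continue
            variants.append(
                FeatureVariant(
                    position=end,
                    wild=m.group(1),
                    mutant=m.group(2),
                    category=category,
                    description=note,
                )
            )
        records.append(
            ProteinRecord(
                entry_id=sp.entry_name,
                accessions=list(sp.accessions),
                expressions=exprs,
                sequence=sp.sequence.upper(),
                feature_variants=variants,
            )
        )
    if not records:
        raise RecordError("no Swiss-Prot entries found in input")
    return records


# ---------------------------------------------------------------------------
# FASTA sequence / alignment resolution
# ---------------------------------------------------------------------------

def _record_index(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for rec in records:
        for ident in rec.identifiers():
            index[ident.upper()] = rec
    return index


def resolve_identifier(token: str, records: Iterable[ProteinRecord]) -> ProteinRecord:
    """Resolve an entry name, accession, or ``sp|ACC|NAME`` header token."""
    index = _record_index(records)
    candidates = [token] + token.split("|")
    for cand in candidates:
        rec = index.get(cand.strip().upper())
        if rec is not None:
            return rec
    raise AlignmentError(f"identifier {token!r} does not resolve to any record")


def parse_fasta_alignment(
    stream: TextIO | str, records: list[ProteinRecord]
) -> Alignment:
    """Read a FASTA sequence or MSA whose headers carry record identifiers.

    A single sequence yields a one-row alignment.  Gap characters are
    ``-`` and ``.``; every de-gapped row must reproduce its record's
    sequence exactly.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    rows: list[tuple[ProteinRecord, str]] = []
    for seq_rec in SeqIO.parse(handle, "fasta"):
        rec = resolve_identifier(seq_rec.id, records)
        rows.append((rec, str(seq_rec.seq)))
    if not rows:
        raise AlignmentError("no FASTA sequences found in input")
    lengths = {len(g) for _, g in rows}
    if len(lengths) != 1:
        detail = ", ".join(f"{r.entry_id}={len(g)}" for r, g in rows)
        raise AlignmentError(f"ragged alignment rows: {detail}")
    return Alignment(rows=rows, columns=lengths.pop())


# ---------------------------------------------------------------------------
# keyword filtering and query construction
# ---------------------------------------------------------------------------

def significant_token(token: str, exempt_tokens: frozenset[str] = frozenset()) -> bool:
    """Apply the query-word significance filter to one token.

    Words of one or two characters are ignored; three-character words are
    kept only if they contain a digit (so gene symbols like ``NR1``
    survive while noise like ``GPA``-style three-letter words is dropped);
    longer words are always kept.  ``exempt_tokens`` bypasses the filter
    for configured gene-name tokens.
    """
    if token.upper() in exempt_tokens:
        return True
    if len(token) <= 2:
        return False
    if len(token) == 3:
        return any(c.isdigit() for c in token)
    return True


def filter_keywords(
    expressions: Iterable[Expression],
    exempt_tokens: Iterable[str] = (),
) -> list[str]:
    """Build the deduplicated query-keyword list from name expressions.

    Each expression is filtered token-wise; an expression whose tokens are
    all dropped contributes nothing.  Surviving multi-token expressions
    become (quoted-phrase) keywords, single tokens become single keywords.
    Output is uppercase, deduplicated, in input order.
    """
    exempt = frozenset(t.upper() for t in exempt_tokens)
    keywords: list[str] = []
    seen: set[str] = set()
    for expr in expressions:
        kept = [w for w in expr.words if significant_token(w, exempt)]
        if not kept:
            continue
        keyword = " ".join(kept)
        if keyword not in seen:
            seen.add(keyword)
            keywords.append(keyword)
    return keywords


def emit_pubmed_query(keywords: list[str]) -> str:
    """OR-join quoted keywords into an E-utilities ``term`` string."""
    if not keywords:
        raise ValueError("cannot build a query from an empty keyword list")
    return " OR ".join(f'"{k}"' for k in keywords)


# ---------------------------------------------------------------------------
# the user-editable expression file
# ---------------------------------------------------------------------------

def write_expression_file(records: Iterable[ProteinRecord], stream: TextIO) -> None:
    """Write the effective expression sets as TSV (identifier, text, source)."""
    for rec in records:
        for expr in rec.expressions:
            stream.write(f"{rec.entry_id}\t{expr.text}\t{expr.source}\n")


def read_expression_file(stream: TextIO | str, records: list[ProteinRecord]) -> None:
    """Replace every record's expression set with the file's contents.

    Inverse of :func:`write_expression_file`: loading a written file
    reproduces the identical expression sets.
    """
    text = stream if isinstance(stream, str) else stream.read()
    index = _record_index(records)
    fresh: dict[str, list[Expression]] = {rec.entry_id: [] for rec in records}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"expression file line {lineno}: expected 3 TSV fields")
        ident, expr_text, source = parts
        rec = index.get(ident.strip().upper())
        if rec is None:
            raise ValueError(f"expression file line {lineno}: unknown identifier {ident!r}")
        fresh[rec.entry_id].append(Expression.from_text(expr_text, source))
    for rec in records:
        rec.expressions = fresh[rec.entry_id]


def load_user_expressions(stream: TextIO | str, records: list[ProteinRecord]) -> None:
    """Append user-supplied expressions from a two-column TSV.

    Each line is ``<entry name or accession><TAB><expression text>``;
    unknown identifiers raise with the offending line number.
    """
    text = stream if isinstance(stream, str) else stream.read()
    index = _record_index(records)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"user expression file line {lineno}: expected '<id>\\t<expression>'"
            )
        ident, expr_text = parts
        rec = index.get(ident.strip().upper())
        if rec is None:
            raise ValueError(
                f"user expression file line {lineno}: unknown identifier {ident!r}"
            )
        rec.expressions.append(Expression.from_text(expr_text, "user"))
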