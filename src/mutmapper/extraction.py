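"""Sentence splitting and point-mutation mention extraction.

Mentions are reported in wNm form: wild-type residue ``w``, 1-based
sequence position ``N``, mutant residue ``m`` (e.g. ``A123G``).  The
extractor is deliberately permissive — tokens shaped like mutations but
naming cell lines (``T47D``) or nucleotide changes are extracted too and
left for the mapping stage to reject as true negatives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Medline

from .alphabet import CANONICAL_AA, THREE_TO_ONE

# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

#: Abbreviations after which a period never ends a sentence.  Fixed and
#: versioned here so sentence indices are reproducible.
SENTENCE_GUARDS: tuple[str, ...] = (
    "e.g",
    "i.e",
    "et al",
    "fig",
    "figs",
    "vs",
    "cf",
    "approx",
    "ref",
    "eq",
)

_SPLIT_POINT = re.compile(r"([.!?])(\s+)(?=[A-Z0-9])")
_SINGLE_UPPER_ABBREV = re.compile(r"(?:^|[^A-Za-z0-9])[A-Z]\.$")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return ordered, non-overlapping half-open character spans of sentences.

    Splits after ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter or digit.  Guards: no split after a single uppercase
    letter (initials) or after the abbreviations in
    :data:`SENTENCE_GUARDS`; a period with no following whitespace never
    splits, which protects tokens like ``p.A123G``.  Text with no
    terminator is one sentence.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SPLIT_POINT.finditer(text):
        end = m.start() + 1  # include the terminator
        if m.group(1) == ".":
            # only the last few characters matter for the guards
            tail = text[max(0, end - 12):end]
            if _SINGLE_UPPER_ABBREV.search(tail):
                continue
            low = tail.lower()
            if any(low.endswith(g + ".") for g in SENTENCE_GUARDS):
                continue
        spans.append((start, end))
        start = m.end()
    tail = text[start:].strip()
    if tail:
        # trim leading whitespace from the final span
        lead = len(text[start:]) - len(text[start:].lstrip())
        spans.append((start + lead, start + len(text[start:].rstrip())))
    return spans


@dataclass
class Document:
    """An abstract (or any text) with its sentence segmentation.

    The title, when present, is simply the first sentence (index 0).
    """

    doc_id: str
    text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_text(cls, doc_id: str, text: str) -> "Document":
        return cls(doc_id=doc_id, text=text, sentences=split_sentences(text))

    def sentence_text(self, index: int) -> str:
        start, end = self.sentences[index]
        return self.text[start:end]


# ---------------------------------------------------------------------------
# mention extraction
# ---------------------------------------------------------------------------

@dataclass
class MutationMention:
    """One extracted wNm candidate with full provenance."""

    wild: str
    position: int
    mutant: str
    doc_id: str
    sentence_index: int
    span: tuple[int, int]
    raw: str
    #: additional spans of the same (doc, wNm) key collected by deduplication
    secondary_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def wnm(self) -> str:
        return f"{self.wild}{self.position}{self.mutant}"


_AA3 = "|".join(THREE_TO_ONE)  # Ala|Arg|...
_LB = r"(?<![A-Za-z0-9])"
_RB = r"(?![A-Za-z0-9])"
_ARROW = r"(?:\s*(?:-+>|→)\s*)"

#: Pattern families, tried in order; overlapping later matches are dropped.
_PATTERNS: tuple[re.Pattern, ...] = (
    # Trp123 -> Met / Trp123 to Met
    re.compile(
        _LB + rf"(?P<w>{_AA3})(?P<p>\d+)(?:{_ARROW}|\s+to\s+)(?P<m>{_AA3})" + _RB,
        re.IGNORECASE,
    ),
    # Trp123Met
    re.compile(_LB + rf"(?P<w>{_AA3})(?P<p>\d+)(?P<m>{_AA3})" + _RB, re.IGNORECASE),
    # W123 -> M (one-letter codes must be uppercase)
    re.compile(_LB + rf"(?P<w>[A-Z])(?P<p>\d+){_ARROW}(?P<m>[A-Z])" + _RB),
    # W123M
    re.compile(_LB + r"(?P<w>[A-Z])(?P<p>\d+)(?P<m>[A-Z])" + _RB),
)


def _normalize_residue(code: str) -> str | None:
    if len(code) == 1:
        return code if code in CANONICAL_AA else None
    return THREE_TO_ONE.get(code.capitalize())


def _normalize_groups(w: str, p: str, m: str) -> tuple[str, int, str] | None:
    wild = _normalize_residue(w)
    mutant = _normalize_residue(m)
    position = int(p)  # leading zeros normalize away
    if wild is None or mutant is None or wild == mutant or position < 1:
        return None
    return wild, position, mutant


def normalize_mention(raw: str) -> str | None:
    """Normalize a raw matched string to canonical wNm, or None if unmappable.

    Idempotent on already-normalized wNm strings.
    """
    for pattern in _PATTERNS:
        m = pattern.fullmatch(raw.strip())
        if m:
            norm = _normalize_groups(m.group("w"), m.group("p"), m.group("m"))
            if norm:
                wild, position, mutant = norm
                return f"{wild}{position}{mutant}"
    return None


def extract_mentions(doc: Document) -> list[MutationMention]:
    """Extract every wNm-shaped mention, sentence by sentence.

    Matches are anchored at word-ish boundaries (start/end of text or any
    non-alphanumeric character) so hyphen-appended forms like
    ``Y1472F-KI`` still match.  Matches whose residues fall outside the
    20 canonical codes (``V125X``) are discarded.  No match crosses a
    sentence boundary.
    """
    mentions: list[MutationMention] = []
    for si, (start, end) in enumerate(doc.sentences):
        sentence = doc.text[start:end]
        taken: list[tuple[int, int]] = []
        for pattern in _PATTERNS:
            for m in pattern.finditer(sentence):
                span = (m.start(), m.end())
                if any(span[0] < t1 and t0 < span[1] for t0, t1 in taken):
                    continue
                norm = _normalize_groups(m.group("w"), m.group("p"), m.group("m"))
                if norm is None:
                    continue
                taken.append(span)
                wild, position, mutant = norm
                mentions.append(
                    MutationMention(
                        wild=wild,
                        position=position,
                        mutant=mutant,
                        doc_id=doc.doc_id,
                        sentence_index=si,
                        span=(start + span[0], start + span[1]),
                        raw=m.group(0),
                    )
                )
    mentions.sort(key=lambda m: m.span)
    return mentions


def dedupe_mentions(mentions: list[MutationMention]) -> list[MutationMention]:
    """Collapse to one representative per (doc_id, wNm), keeping the first.

    Later occurrences' spans are retained on the representative as
    secondary evidence.  All mentions must share one doc_id.
    """
    if not mentions:
        return []
    doc_ids = {m.doc_id for m in mentions}
    if len(doc_ids) > 1:
        raise ValueError(f"dedupe_mentions got mixed doc_ids: {sorted(doc_ids)}")
    by_key: dict[str, MutationMention] = {}
    for mention in sorted(mentions, key=lambda m: m.span):
        rep = by_key.get(mention.wnm)
        if rep is None:
            by_key[mention.wnm] = mention
        else:
            rep.secondary_spans.append(mention.span)
    return list(by_key.values())


# ---------------------------------------------------------------------------
# corpus readers
# ---------------------------------------------------------------------------

def read_corpus_dir(path: str | Path) -> list[Document]:
    """One document per ``*.txt`` file; the file stem is the doc_id."""
    docs = []
    for file in sorted(Path(path).glob("*.txt")):
        docs.append(Document.from_text(file.stem, file.read_text().strip()))
    return docs


def read_medline(path: str | Path) -> list[Document]:
    """MEDLINE-format records: PMID is the doc_id, title + abstract the text."""
    docs = []
    with open(path) as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID")
            if not pmid:
                continue
            parts = [rec.get("TI", ""), rec.get("AB", "")]
            text = " ".join(p.strip() for p in parts if p and p.strip())
            if text:
                docs.append(Document.from_text(pmid, text))
    return docs


def read_corpus(path: str | Path) -> list[Document]:
    """Dispatch on path type: directory of .txt files, or a MEDLINE file."""
    path = Path(path)
    if path.is_dir():
        return read_corpus_dir(path)
    return read_medline(path)
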