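"""The mutation-to-protein mapping engine.

For each extracted mention the engine decides which query protein(s) it
belongs to, with three possible outcomes:

* ``mapped`` — the mention validates on exactly one candidate protein;
* ``non_mapped`` — no protein name is found in the abstract, or the
  wild-type residue does not occupy the stated position in any named
  protein's sequence;
* ``multi_mapped`` — the mention validates on several candidates and the
  ±1-sentence disambiguation window cannot reduce them to one.

Candidate discovery is abstract-wide; the sentence window (the sentence
holding the mention plus ``window_radius`` sentences either side) is a
refinement applied only when several candidates validate.  Two
expression-matching modes are supported: high precision (all of an
expression's significant words must appear in a sentence) and high
recall (two or more words suffice; single-word expressions such as
``PTEN`` require that word in both modes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .extraction import Document, MutationMention, dedupe_mentions, extract_mentions
from .records import Expression, ProteinRecord, significant_token, tokenize_expression

logger = logging.getLogger(__name__)

MODES = ("precision", "recall")
STATUSES = ("mapped", "non_mapped", "multi_mapped")
ORIGINS = ("literature", "uniprot_annotation")


@dataclass(frozen=True)
class EngineConfig:
    mode: str = "precision"
    window_radius: int = 1
    significance_filter: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")


@dataclass(frozen=True)
class ExpressionHit:
    """A protein expression found (fully or partially) in one sentence."""

    record: ProteinRecord
    expression: Expression
    sentence_index: int
    matched_words: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.matched_words:
            raise ValueError("an ExpressionHit must match at least one word")
        if not set(self.matched_words) <= set(self.expression.words):
            raise ValueError("matched_words must be a subset of the expression words")


@dataclass
class MappingResult:
    mention: MutationMention
    status: str
    matched: list[tuple[ProteinRecord, int]]
    mode: str
    evidence: list[ExpressionHit] = field(default_factory=list)
    origin: str = "literature"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        n = len(self.matched)
        ok = (
            (self.status == "non_mapped" and n == 0)
            or (self.status == "mapped" and n == 1)
            or (self.status == "multi_mapped" and n >= 2)
        )
        if not ok:
            raise ValueError(
                f"status {self.status} inconsistent with {n} matched proteins"
            )
        for rec, pos in self.matched:  # soundness: every match validates
            if not validate_position(rec, self.mention):
                raise ValueError(
                    f"unsound match: {self.mention.wnm} does not validate on "
                    f"{rec.entry_id}"
                )

    @property
    def matched_ids(self) -> list[str]:
        return [rec.entry_id for rec, _ in self.matched]


# ---------------------------------------------------------------------------
# expression matching
# ---------------------------------------------------------------------------

def _matching_words(expr: Expression, use_filter: bool) -> list[str]:
    words = list(dict.fromkeys(expr.words))  # unique, order-preserving
    if use_filter:
        words = [w for w in words if significant_token(w)]
    return words


def match_expressions(
    doc: Document,
    records: Sequence[ProteinRecord],
    mode: str = "precision",
    significance_filter: bool = True,
) -> list[ExpressionHit]:
    """Whole-word, case-insensitive expression search, sentence by sentence.

    Precision mode requires all of an expression's (significant) words in
    the sentence; recall mode requires at least two of them.  Word order
    and adjacency are ignored.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    hits: list[ExpressionHit] = []
    for si in range(len(doc.sentences)):
        tokens = set(tokenize_expression(doc.sentence_text(si)))
        if not tokens:
            continue
        for rec in records:
            for expr in rec.expressions:
                words = _matching_words(expr, significance_filter)
                if not words:
                    continue
                matched = tuple(w for w in words if w in tokens)
                if mode == "precision":
                    ok = len(matched) == len(words)
                else:
                    ok = len(matched) >= 2 or (len(words) == 1 and bool(matched))
                if ok:
                    hits.append(ExpressionHit(rec, expr, si, matched))
    return hits


def validate_position(record: ProteinRecord, mention: MutationMention) -> bool:
    """True iff the wild-type residue occupies the mention's 1-based position."""
    if not 1 <= mention.position <= len(record.sequence):
        return False
    return record.sequence[mention.position - 1] == mention.wild


# ---------------------------------------------------------------------------
# the mapping algorithm
# ---------------------------------------------------------------------------

def map_mention(
    doc: Document,
    mention: MutationMention,
    records: Sequence[ProteinRecord],
    config: EngineConfig = EngineConfig(),
    hits: list[ExpressionHit] | None = None,
) -> MappingResult:
    """Assign one mention to mapped / non_mapped / multi_mapped.

    Candidates are the records named anywhere in the abstract on whose
    sequence the mention validates.  With several candidates, only those
    named within the sentence window around the mention are kept; if the
    window still holds several — or names none of them — the result is
    multi_mapped.
    """
    if hits is None:
        hits = match_expressions(
            doc, records, config.mode, config.significance_filter
        )
    hit_sentences: dict[str, set[int]] = {}
    for hit in hits:
        hit_sentences.setdefault(hit.record.entry_id, set()).add(hit.sentence_index)

    candidates = [
        rec
        for rec in records
        if rec.entry_id in hit_sentences and validate_position(rec, mention)
    ]
    if not candidates:
        return MappingResult(mention, "non_mapped", [], config.mode, [])
    if len(candidates) == 1:
        chosen = candidates
    else:
        lo = mention.sentence_index - config.window_radius
        hi = mention.sentence_index + config.window_radius
        in_window = [
            rec
            for rec in candidates
            if any(lo <= si <= hi for si in hit_sentences[rec.entry_id])
        ]
        if len(in_window) == 1:
            chosen = in_window
        elif len(in_window) >= 2:
            chosen = in_window
        else:
            # no candidate named inside the window: keep the abstract-level set
            chosen = candidates
    status = "mapped" if len(chosen) == 1 else "multi_mapped"
    chosen_ids = {rec.entry_id for rec in chosen}
    evidence = [h for h in hits if h.record.entry_id in chosen_ids]
    matched = [(rec, mention.position) for rec in chosen]
    return MappingResult(mention, status, matched, config.mode, evidence)


def map_document(
    doc: Document,
    records: Sequence[ProteinRecord],
    config: EngineConfig = EngineConfig(),
) -> list[MappingResult]:
    """Extract, deduplicate and map every mention of one document."""
    mentions = dedupe_mentions(extract_mentions(doc))
    hits = match_expressions(doc, records, config.mode, config.significance_filter)
    return [map_mention(doc, m, records, config, hits) for m in mentions]


def map_corpus(
    docs: Iterable[Document],
    records: Sequence[ProteinRecord],
    config: EngineConfig = EngineConfig(),
) -> list[MappingResult]:
    """Map every document's deduplicated mentions, deterministically ordered."""
    results: list[MappingResult] = []
    n_docs = 0
    for doc in sorted(docs, key=lambda d: d.doc_id):
        n_docs += 1
        results.extend(map_document(doc, records, config))
    results.sort(key=lambda r: (r.mention.doc_id, r.mention.position, r.mention.wnm))
    counts = {s: sum(1 for r in results if r.status == s) for s in STATUSES}
    logger.info(
        "mapped corpus: %d documents, %d mentions (%d mapped, %d non-mapped, "
        "%d multi-mapped), mode=%s",
        n_docs,
        len(results),
        counts["mapped"],
        counts["non_mapped"],
        counts["multi_mapped"],
        config.mode,
    )
    return results


def map_uniprot_features(records: Sequence[ProteinRecord]) -> list[MappingResult]:
    """Overlay the feature-table substitutions as already-mapped results.

    Natural variants and mutagenesis annotations need no text evidence:
    each becomes a mapped result on its own record, flagged with origin
    ``uniprot_annotation`` so reports can distinguish them from
    literature-derived mutations.
    """
    results: list[MappingResult] = []
    for rec in records:
        for fv in rec.feature_variants:
            mention = MutationMention(
                wild=fv.wild,
                position=fv.position,
                mutant=fv.mutant,
                doc_id=f"uniprot:{rec.entry_id}",
                sentence_index=0,
                span=(0, 0),
                raw=f"{fv.wild}{fv.position}{fv.mutant}",
            )
            results.append(
                MappingResult(
                    mention,
                    "mapped",
                    [(rec, fv.position)],
                    mode="precision",
                    evidence=[],
                    origin="uniprot_annotation",
                )
            )
    return results
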