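"""Confusion-matrix scoring of mapping output against gold annotations.

Per deduplicated mention (one (doc, wNm) key each):

* mapped or multi-mapped with the true protein among the matched set — tp
  (a multi-mapped set containing the truth counts as correct);
* mapped or multi-mapped without it (including mentions that belong to no
  query protein) — fp;
* non-mapped with no true protein — tn;
* non-mapped despite a true protein — fn.

The four scores, as percentages:

    recall    = 100 * tp / (tp + fn)
    precision = 100 * tp / (tp + fp)
    accuracy  = 100 * (tp + tn) / (tp + fp + fn + tn)
    F-measure = 100 * 2 tp / (2 tp + fp + fn)

The reporting helper truncates (never rounds) accuracy, precision and
recall to integer percent and the F-measure to one decimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .mapping import MappingResult

NONE_TARGET = "NONE"


class GoldCoverageError(ValueError):
    """A mapped mention is missing from the gold annotation file."""


@dataclass(frozen=True)
class GoldAnnotation:
    """The truth for one (document, wNm) mention.

    ``true_target`` is a record identifier, or None when the mention does
    not belong to any query protein (gene mutations, cell lines,
    off-target proteins).  ``category`` optionally records why.
    """

    doc_id: str
    wnm: str
    true_target: str | None
    category: str = ""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class Metrics:
    """The four scores as percentages; None marks a zero-denominator score."""

    recall: float | None
    precision: float | None
    accuracy: float | None
    f_measure: float | None


def tally(
    results: Sequence[MappingResult],
    gold: Iterable[GoldAnnotation],
) -> ConfusionCounts:
    """Score every result against gold; unlisted mentions are an error."""
    gold_map = {(g.doc_id, g.wnm): g for g in gold}
    tp = fp = fn = tn = 0
    for res in results:
        key = (res.mention.doc_id, res.mention.wnm)
        if key not in gold_map:
            raise GoldCoverageError(
                f"mention {res.mention.wnm} in {res.mention.doc_id} missing from gold"
            )
        truth = gold_map[key].true_target
        if res.status in ("mapped", "multi_mapped"):
            matched_ids = set()
            for rec, _ in res.matched:
                matched_ids |= rec.identifiers()
            if truth is not None and truth in matched_ids:
                tp += 1
            else:
                fp += 1
        else:
            if truth is None:
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def _score(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def metrics(counts: ConfusionCounts) -> Metrics:
    """The four scores; a zero denominator yields None, not a crash."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return Metrics(
        recall=_score(counts.tp, counts.tp + counts.fn),
        precision=_score(counts.tp, counts.tp + counts.fp),
        accuracy=_score(counts.tp + counts.tn, counts.total),
        f_measure=_score(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
    )


def printed_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Scores at reporting precision: integer percent for recall,
    precision and accuracy; one truncated decimal for the F-measure.

    Exact rational arithmetic avoids float-truncation artifacts.
    """

    def trunc(num: int, den: int, decimals: int) -> float | None:
        if den == 0:
            return None
        scaled = Fraction(100 * num, den) * 10**decimals
        return math.floor(scaled) / 10**decimals

    return {
        "recall": trunc(counts.tp, counts.tp + counts.fn, 0),
        "precision": trunc(counts.tp, counts.tp + counts.fp, 0),
        "accuracy": trunc(counts.tp + counts.tn, counts.total, 0),
        "f_measure": trunc(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, 1),
    }


# ---------------------------------------------------------------------------
# gold file I/O
# ---------------------------------------------------------------------------

def read_gold(stream: TextIO | str) -> list[GoldAnnotation]:
    """Gold TSV: doc_id, wNm, true_target (or NONE), optional category."""
    text = stream if isinstance(stream, str) else stream.read()
    gold: list[GoldAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (3, 4):
            raise ValueError(f"gold line {lineno}: expected 3 or 4 TSV fields")
        doc_id, wnm, target = parts[:3]
        category = parts[3] if len(parts) == 4 else ""
        gold.append(
            GoldAnnotation(
                doc_id=doc_id,
                wnm=wnm,
                true_target=None if target == NONE_TARGET else target,
                category=category,
            )
        )
    return gold


def write_gold(gold: Iterable[GoldAnnotation], stream: TextIO) -> None:
    for g in gold:
        target = NONE_TARGET if g.true_target is None else g.true_target
        stream.write(f"{g.doc_id}\t{g.wnm}\t{target}\t{g.category}\n")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report_evaluation(
    results: Sequence[MappingResult],
    gold: Iterable[GoldAnnotation],
) -> pd.DataFrame:
    """Corpus-level and per-record breakdown of counts and scores.

    A record's row counts mentions whose truth is that record (tp/fn)
    plus mentions wrongly mapped onto it (fp); true negatives belong to
    no record and appear only in the ALL row.
    """
    gold = list(gold)
    if not results and not gold:
        raise ValueError("nothing to evaluate: no results and no gold")
    gold_map = {(g.doc_id, g.wnm): g for g in gold}
    per_record: dict[str, dict[str, int]] = {}

    def bump(record_id: str, kind: str) -> None:
        row = per_record.setdefault(record_id, {"tp": 0, "fp": 0, "fn": 0, "tn": 0})
        row[kind] += 1

    for res in results:
        key = (res.mention.doc_id, res.mention.wnm)
        if key not in gold_map:
            raise GoldCoverageError(
                f"mention {res.mention.wnm} in {res.mention.doc_id} missing from gold"
            )
        truth = gold_map[key].true_target
        if res.status in ("mapped", "multi_mapped"):
            matched_ids = set()
            for rec, _ in res.matched:
                matched_ids |= rec.identifiers()
            if truth is not None and truth in matched_ids:
                bump(truth, "tp")
            else:
                for rec, _ in res.matched:
                    bump(rec.entry_id, "fp")
        elif truth is not None:
            bump(truth, "fn")

    corpus = tally(results, gold)
    rows = []
    for record_id in sorted(per_record):
        c = ConfusionCounts(**per_record[record_id])
        rows.append({"record": record_id, **per_record[record_id], **printed_metrics(c)})
    rows.append(
        {
            "record": "ALL",
            "tp": corpus.tp,
            "fp": corpus.fp,
            "fn": corpus.fn,
            "tn": corpus.tn,
            **printed_metrics(corpus),
        }
    )
    return pd.DataFrame(rows)


def write_evaluation(frame: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    (outdir / "evaluation.json").write_text(
        json.dumps(frame.to_dict(orient="records"), indent=2) + "\n"
    )
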