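"""Project mapping results onto alignment columns and render reports.

A column of a multiple sequence alignment collects structurally or
evolutionarily equivalent positions, so mutations performed at
equivalent positions in related proteins land on the same column.
Aggregation is per column, not per residue identity: different amino
acids in one column are co-reported.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .mapping import MappingResult
from .records import GAP_CHARS, Alignment, AlignmentError, ProteinRecord

GAP = None  # gap marker returned by position_for_column


def column_for_position(row: str, position: int) -> int:
    """1-based alignment column holding the ``position``-th non-gap residue."""
    count = 0
    for col, char in enumerate(row, start=1):
        if char not in GAP_CHARS:
            count += 1
            if count == position:
                return col
    raise ValueError(
        f"position {position} out of range for a row of {count} residues"
    )


def position_for_column(row: str, column: int):
    """Residue position at ``column``, or the gap marker (None) on gap cells."""
    if not 1 <= column <= len(row):
        raise ValueError(f"column {column} out of range 1..{len(row)}")
    if row[column - 1] in GAP_CHARS:
        return GAP
    return sum(1 for c in row[:column] if c not in GAP_CHARS)


@dataclass
class ColumnAnnotation:
    """All mapping results landing on one alignment column.

    Each entry corresponds to one (result, matched record) pair, so a
    multi-mapped result contributes one entry per matched record and the
    total entry count across annotations equals the pair count.
    """

    column: int
    entries: list[tuple[ProteinRecord, int, list[MappingResult]]]


def overlay(
    alignment: Alignment, results: Sequence[MappingResult]
) -> list[ColumnAnnotation]:
    """One :class:`ColumnAnnotation` per column that received >=1 result.

    Literature and feature-table origins are both carried through.
    """
    entries: list[tuple[int, ProteinRecord, int, MappingResult]] = []
    for result in results:
        for rec, position in result.matched:
            try:
                row = alignment.row_for(rec)
            except AlignmentError:
                raise AlignmentError(
                    f"result for {result.mention.wnm} references record "
                    f"{rec.entry_id} absent from the alignment"
                ) from None
            col = column_for_position(row, position)
            entries.append((col, rec, position, result))
    entries.sort(key=lambda e: (e[0], e[1].entry_id, e[2], e[3].mention.doc_id))
    annotations: dict[int, ColumnAnnotation] = {}
    for col, rec, position, result in entries:
        ann = annotations.setdefault(col, ColumnAnnotation(column=col, entries=[]))
        ann.entries.append((rec, position, [result]))
    return [annotations[c] for c in sorted(annotations)]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _cell_marker(results: list[MappingResult]) -> str:
    origins = {r.origin for r in results}
    statuses = {r.status for r in results}
    if origins == {"uniprot_annotation"}:
        return "u"
    if "multi_mapped" in statuses:
        return "+"
    return "*"


def _markers_by_cell(
    annotations: Sequence[ColumnAnnotation],
) -> dict[tuple[str, int], str]:
    cell_results: dict[tuple[str, int], list[MappingResult]] = {}
    for ann in annotations:
        for rec, _, results in ann.entries:
            cell_results.setdefault((rec.entry_id, ann.column), []).extend(results)
    return {cell: _cell_marker(res) for cell, res in cell_results.items()}


def render_text(alignment: Alignment, annotations: Sequence[ColumnAnnotation]) -> str:
    """Plain-text alignment with marker lines and a per-column legend.

    Markers: ``*`` literature mapped, ``+`` multi-mapped involved,
    ``u`` feature-table annotation only.
    """
    ann_by_col = {a.column: a for a in annotations}
    marker_by_cell = _markers_by_cell(annotations)
    width = max((len(rec.entry_id) for rec, _ in alignment.rows), default=10) + 2
    block = 60
    lines: list[str] = []
    for offset in range(0, alignment.columns, block):
        hi = min(offset + block, alignment.columns)
        lines.append("{:<{}}columns {}-{}".format("", width, offset + 1, hi))
        for rec, row in alignment.rows:
            lines.append("{:<{}}{}".format(rec.entry_id, width, row[offset:hi]))
            markers = "".join(
                marker_by_cell.get((rec.entry_id, col), " ")
                for col in range(offset + 1, hi + 1)
            )
            if markers.strip():
                lines.append("{:<{}}{}".format("", width, markers))
        lines.append("")
    lines.append("Legend (column: record position status [doc ...])")
    for col in sorted(ann_by_col):
        for rec, position, results in ann_by_col[col].entries:
            for res in results:
                lines.append(
                    f"  {col}: {rec.entry_id} {rec.sequence[position - 1]}{position} "
                    f"{res.mention.wnm} {res.status} [{res.mention.doc_id}]"
                )
    return "\n".join(lines) + "\n"


_HTML_HEAD = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>MutationMapper report</title>
<style>
body { font-family: sans-serif; margin: 2em; }
pre.aln { font-family: monospace; line-height: 1.4; }
span.mapped { background: #8f8; }
span.multi_mapped { background: #fd8; }
span.uniprot { background: #8cf; }
td, th { border: 1px solid #ccc; padding: 2px 8px; font-size: 90%; }
table { border-collapse: collapse; }
</style></head><body>
<h1>Mutation mapping report</h1>
<p>Highlight key: <span class="key mapped">mapped</span>
<span class="key multi_mapped">multi-mapped</span>
<span class="key uniprot">UniProt annotation</span></p>
"""


def render_html(
    alignment: Alignment,
    annotations: Sequence[ColumnAnnotation],
    results: Sequence[MappingResult],
) -> str:
    """Self-contained static HTML: highlighted alignment plus detail table."""
    classes = {"*": "mapped", "+": "multi_mapped", "u": "uniprot"}
    marker_by_cell = _markers_by_cell(annotations)
    parts = [_HTML_HEAD]
    parts.append('<pre class="aln">')
    for rec, row in alignment.rows:
        cells = []
        for col, char in enumerate(row, start=1):
            marker = marker_by_cell.get((rec.entry_id, col))
            if marker:
                css = classes[marker]
                cells.append(
                    f'<span class="{css}"><a href="#c{col}" '
                    f'style="color:inherit;text-decoration:none">{html.escape(char)}</a></span>'
                )
            else:
                cells.append(html.escape(char))
        parts.append(f"{html.escape(rec.entry_id):<14}{''.join(cells)}")
    parts.append("</pre>")
    parts.append("<h2>Annotated columns</h2>")
    parts.append(
        "<table><tr><th>column</th><th>record</th><th>position</th>"
        "<th>mutation</th><th>status</th><th>origin</th><th>document</th>"
        "<th>evidence</th></tr>"
    )
    for ann in annotations:
        for rec, position, cell_results in ann.entries:
            for res in cell_results:
                sentences = sorted({h.sentence_index for h in res.evidence})
                parts.append(
                    f'<tr id="c{ann.column}"><td>{ann.column}</td>'
                    f"<td>{html.escape(rec.entry_id)}</td><td>{position}</td>"
                    f"<td>{res.mention.wnm}</td><td>{res.status}</td>"
                    f"<td>{res.origin}</td>"
                    f"<td>{html.escape(res.mention.doc_id)}</td>"
                    f"<td>sentences {sentences}</td></tr>"
                )
    parts.append("</table></body></html>")
    return "\n".join(parts) + "\n"


@dataclass(frozen=True)
class Report:
    text: str
    html: str
    columns_tsv: str


def render_report(
    alignment: Alignment,
    annotations: Sequence[ColumnAnnotation],
    results: Sequence[MappingResult],
) -> Report:
    """Render all report artifacts; a pure function of its inputs."""
    tsv_lines = ["column\trecord\tposition\twNm\tstatus\tdoc_id"]
    for ann in annotations:
        for rec, position, cell_results in ann.entries:
            for res in cell_results:
                tsv_lines.append(
                    f"{ann.column}\t{rec.entry_id}\t{position}\t"
                    f"{res.mention.wnm}\t{res.status}\t{res.mention.doc_id}"
                )
    return Report(
        text=render_text(alignment, annotations),
        html=render_html(alignment, annotations, results),
        columns_tsv="\n".join(tsv_lines) + "\n",
    )


def write_report(report: Report, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignment.aln.txt").write_text(report.text)
    (outdir / "report.html").write_text(report.html)
    (outdir / "columns.tsv").write_text(report.columns_tsv)
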