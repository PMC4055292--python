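"""Serialization of a merged map and programmatic browsing features.

The two primary exports mirror the tool's tabulated deliverables: a
tab-separated Txt file (reloadable — the sentinel block makes it a valid
input for a later run) and a self-contained HTML document whose entity
cells link out to the NCBI/Ensembl/UCSC records.  BED6 and FASTA exports
interchange with genome browsers; summaries and term search replace the
interactive region browsers with library calls.
"""

from __future__ import annotations

import html
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from pyfaidx import Fasta

from .ingest import FORMAT_VERSION, SENTINEL, TXT_COLUMNS, AnnotatedEntry
from .library import chrom_sort_key, span_length
from .merge import MergedMap, RegionalUnit

__all__ = [
    "UrlTemplates",
    "SummaryTable",
    "write_txt",
    "write_html",
    "export_bed",
    "summarize",
    "search_units",
    "extract_unit_fasta",
]


@dataclass
class UrlTemplates:
    """Outbound link patterns for the three public databases.

    Placeholders ``{symbol}``, ``{chrom}``, ``{start}``, ``{end}`` are
    substituted per entry; each pattern must contain at least one.
    """

    ncbi: str = "https://www.ncbi.nlm.nih.gov/gene/?term={symbol}"
    ensembl: str = ("https://www.ensembl.org/Homo_sapiens/Location/View"
                    "?r={chrom}:{start}-{end}")
    ucsc: str = ("https://genome.ucsc.edu/cgi-bin/hgTracks"
                 "?position=chr{chrom}:{start}-{end}")

    def __post_init__(self) -> None:
        placeholders = ("{symbol}", "{chrom}", "{start}", "{end}")
        for name in ("ncbi", "ensembl", "ucsc"):
            pattern = getattr(self, name)
            if not any(p in pattern for p in placeholders):
                raise ValueError(f"URL template '{name}' has no placeholder")

    def links_for(self, entry: AnnotatedEntry) -> list[tuple[str, str]]:
        subs = {
            "symbol": entry.assigned_gene or "",
            "chrom": entry.resolved_chrom or "",
            "start": entry.resolved_start or "",
            "end": entry.resolved_end or "",
        }
        out = []
        for name in ("ncbi", "ensembl", "ucsc"):
            out.append((name, getattr(self, name).format(**subs)))
        return out


def _passthrough_columns(m: MergedMap) -> list[str]:
    """Union of passthrough columns, dataset load order first-wins."""
    ordered: list[str] = []
    specs = m.provenance.get("datasets") or []
    for spec in specs:
        for col in spec.get("passthrough", []):
            if col not in ordered:
                ordered.append(col)
    for _, entry in m.iter_entries():
        for col in entry.passthrough:
            if col not in ordered:
                ordered.append(col)
    return ordered


def _entry_row(unit: RegionalUnit, entry: AnnotatedEntry,
               is_defining: bool, passthrough: list[str]) -> list[str]:
    gene_ids = "|".join(f"{k}={v}" for k, v in
                        sorted(entry.gene_identifiers.items()))
    gene_span = ""
    if entry.gene_span:
        c, s, e = entry.gene_span
        gene_span = f"{c}:{s}-{e}"
    fixed = [
        unit.chrom if unit.chrom is not None else "",
        str(unit.start_flag) if unit.start_flag is not None else "",
        str(unit.stop_flag) if unit.stop_flag is not None else "",
        str(entry.resolved_start) if entry.resolved_start is not None else "",
        str(entry.resolved_end) if entry.resolved_end is not None else "",
        entry.entity_name or "",
        entry.data_type,
        "1" if is_defining else "0",
        entry.dataset_id,
        entry.assigned_gene or "",
        gene_ids,
        gene_span,
        entry.resolution,
        entry.ambiguity_note or "",
    ]
    return fixed + [entry.passthrough.get(c, "") for c in passthrough]


def _table_rows(m: MergedMap) -> tuple[list[str], list[list[str]]]:
    passthrough = _passthrough_columns(m)
    header = TXT_COLUMNS + passthrough
    rows = []
    for unit in m.units:
        rows.append(_entry_row(unit, unit.defining_entry, True, passthrough))
        for sub in unit.subregions:
            rows.append(_entry_row(unit, sub, False, passthrough))
    return header, rows


def _sentinel_lines(m: MergedMap, deterministic: bool) -> list[str]:
    fields = [f"format={FORMAT_VERSION}", "tool=regionamalgam", "version=0.1.0"]
    if m.provenance.get("assembly"):
        fields.append(f"assembly={m.provenance['assembly']}")
    mode = m.provenance.get("merge_mode", "coords")
    fields.append(f"mode={mode}")
    if not deterministic:
        fields.append(f"written={time.strftime('%Y-%m-%dT%H:%M:%S')}")
    lines = [SENTINEL + "\t" + "\t".join(fields)]
    for spec in m.provenance.get("datasets", []):
        lines.append("#dataset\t{id}\t{type}\t{cols}".format(
            id=spec["id"], type=spec["data_type"],
            cols="|".join(spec.get("passthrough", []))))
    return lines


def write_txt(m: MergedMap, path: str | Path,
              deterministic: bool = False) -> Path:
    """Write the merged map as the tab-separated Txt export.

    One row per member entry, defining entry first within its unit; rows
    already arrive in (chromosome order, StartFlag, Start) order from the
    map.  With ``deterministic`` the sentinel omits the timestamp so
    identical inputs produce byte-identical files.
    """
    path = Path(path)
    header, rows = _table_rows(m)
    with open(path, "w", newline="\n") as fh:
        for line in _sentinel_lines(m, deterministic):
            fh.write(line + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


_HTML_STYLE = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; width: 100%; }
th, td { border: 1px solid #bbb; padding: 3px 8px; font-size: 0.85em; }
th { background: #31507a; color: white; }
tr.unit td { background: #dce6f4; font-weight: bold; }
tr.sub td:first-child { padding-left: 2em; }
a { text-decoration: none; }
""".strip()


def write_html(m: MergedMap, path: str | Path,
               templates: UrlTemplates | None = None,
               title: str = "Merged regional units") -> Path:
    """Write a single self-contained HTML document of the merged table.

    Content matches :func:`write_txt`; units get a header row spanning
    their subregion rows, and entity cells whose entry carries a gene
    assignment link to all three database URL templates.  No external
    resources are referenced.
    """
    templates = templates or UrlTemplates()
    path = Path(path)
    passthrough = _passthrough_columns(m)
    cols = ["Start", "Stop", "EntityName", "DataType", "DatasetId"] + passthrough

    def entity_cell(entry: AnnotatedEntry) -> str:
        label = html.escape(entry.entity_name or entry.label)
        if not entry.assigned_gene:
            return label
        anchors = " ".join(
            f'<a href="{html.escape(url, quote=True)}">[{name}]</a>'
            for name, url in templates.links_for(entry)
        )
        return f"{label} {anchors}"

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>{html.escape(title)}</title>",
        f"<style>{_HTML_STYLE}</style></head><body>",
        f"<h1>{html.escape(title)}</h1>",
        f"<p>{len(m.units)} regional units, {m.n_entries} entries, "
        f"{m.unmapped.total} unmapped.</p>",
        "<table>",
        "<tr>" + "".join(f"<th>{html.escape(c)}</th>" for c in cols) + "</tr>",
    ]
    for unit in m.units:
        label = unit.span_label or (unit.key or "")
        parts.append(
            f'<tr class="unit"><td colspan="{len(cols)}">Unit '
            f'{html.escape(label)} &mdash; origin {html.escape(unit.origin_dataset)}'
            f' ({1 + len(unit.subregions)} entries)</td></tr>'
        )
        for entry in unit.members:
            cells = [
                str(entry.resolved_start or ""),
                str(entry.resolved_end or ""),
                entity_cell(entry),
                html.escape(entry.data_type),
                html.escape(entry.dataset_id),
            ] + [html.escape(entry.passthrough.get(c, "")) for c in passthrough]
            cls = "sub" if entry is not unit.defining_entry else "def"
            parts.append(
                f'<tr class="{cls}">' +
                "".join(f"<td>{c}</td>" for c in cells) + "</tr>"
            )
    parts += ["</table>", "</body></html>"]
    path.write_text("\n".join(parts) + "\n")
    return path


def export_bed(m: MergedMap, path: str | Path,
               level: str = "units") -> tuple[Path, int]:
    """Write BED6 lines for units or individual entries.

    BED is 0-based half-open, so the inclusive start is decremented by
    one and the end kept; the conversion is an exact bijection.  Key-mode
    units without coordinates are skipped; the skip count is returned.
    """
    if level not in ("units", "entries"):
        raise ValueError(f"unknown BED level {level!r}")
    path = Path(path)
    skipped = 0
    lines = []
    for unit in m.units:
        if unit.chrom is None:
            skipped += 1
            continue
        if level == "units":
            name = unit.key or unit.defining_entry.label or unit.span_label
            lines.append((unit.chrom, unit.start_flag - 1, unit.stop_flag,
                          name))
        else:
            for entry in unit.members:
                lines.append((unit.chrom, entry.resolved_start - 1,
                              entry.resolved_end, entry.label))
    with open(path, "w", newline="\n") as fh:
        for chrom, start0, end, name in lines:
            fh.write(f"chr{chrom}\t{start0}\t{end}\t{name}\t0\t.\n")
    return path, skipped


@dataclass
class SummaryTable:
    """Per-chromosome unit/entry/coverage accounting plus genome totals."""

    table: pd.DataFrame
    dataset_ids: list[str]
    unmapped_counts: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        if self.unmapped_counts:
            lines.append("")
            lines.append("Unmapped entries:")
            for ds, n in sorted(self.unmapped_counts.items()):
                lines.append(f"  {ds}: {n}")
        return "\n".join(lines)


def summarize(m: MergedMap) -> SummaryTable:
    """Tabulate unit counts, per-dataset entry counts and covered base
    pairs per chromosome, with a genome totals row.

    Covered bp sums the inclusive envelope lengths; units are pairwise
    non-overlapping so this is the exact base-pair coverage.
    """
    ds_ids: list[str] = []
    for spec in m.provenance.get("datasets", []):
        ds_ids.append(spec["id"])
    for _, entry in m.iter_entries():
        if entry.dataset_id not in ds_ids:
            ds_ids.append(entry.dataset_id)

    rows: dict[str, dict] = {}
    for unit in m.units:
        chrom = unit.chrom if unit.chrom is not None else "(no-coords)"
        row = rows.setdefault(chrom, {
            "chrom": chrom, "units": 0, "covered_bp": 0,
            **{ds: 0 for ds in ds_ids}})
        row["units"] += 1
        if unit.chrom is not None:
            row["covered_bp"] += span_length(unit.start_flag, unit.stop_flag)
        for entry in unit.members:
            row[entry.dataset_id] += 1

    ordered = sorted(rows.values(),
                     key=lambda r: ((1, (0, 0, "")) if r["chrom"] == "(no-coords)"
                                    else (0, chrom_sort_key(r["chrom"]))))
    total = {"chrom": "TOTAL",
             "units": sum(r["units"] for r in ordered),
             "covered_bp": sum(r["covered_bp"] for r in ordered),
             **{ds: sum(r[ds] for r in ordered) for ds in ds_ids}}
    ordered.append(total)
    cols = ["chrom", "units"] + ds_ids + ["covered_bp"]
    df = pd.DataFrame(ordered, columns=cols)
    return SummaryTable(table=df, dataset_ids=ds_ids,
                        unmapped_counts=m.unmapped.counts())


def search_units(m: MergedMap, term: str) -> list[RegionalUnit]:
    """Case-insensitive substring search over a map's units.

    Matches entity labels, assigned gene symbols, audit notes, dataset
    ids and the unit's ``chrom:start-stop`` string; results come back in
    map order.
    """
    needle = str(term).strip().lower()
    if not needle:
        raise ValueError("search term must be non-empty")
    hits = []
    for unit in m.units:
        haystack = [unit.span_label, unit.key or ""]
        for entry in unit.members:
            haystack += [entry.label, entry.entity_name or "",
                         entry.assigned_gene or "", entry.ambiguity_note or "",
                         entry.dataset_id]
        if any(needle in h.lower() for h in haystack if h):
            hits.append(unit)
    return hits


def _resolve_seq(fasta: Fasta, chrom: str):
    for candidate in (chrom, f"chr{chrom}"):
        if candidate in fasta:
            return fasta[candidate]
    return None


def extract_unit_fasta(m: MergedMap, reference: str | Path,
                       path: str | Path,
                       level: str = "units") -> tuple[Path, int]:
    """Extract reference sequence for units or for their assigned genes.

    ``units`` emits one record per unit envelope; ``genes`` one record
    per distinct assigned gene (library span, deduplicated across
    entries).  Headers read ``<label>::<chrom>:<start>-<stop>``;
    sequences are the 1-based inclusive substrings, uppercased.  Units
    or genes on chromosomes absent from the reference are skipped and
    counted.
    """
    if level not in ("units", "genes"):
        raise ValueError(f"unknown FASTA level {level!r}")
    fasta = Fasta(str(reference))
    path = Path(path)
    targets: list[tuple[str, str, int, int]] = []
    if level == "units":
        for unit in m.units:
            if unit.chrom is None:
                continue
            label = unit.key or unit.defining_entry.label or unit.span_label
            targets.append((label, unit.chrom, unit.start_flag, unit.stop_flag))
    else:
        seen: dict[tuple, str] = {}
        for _, entry in m.iter_entries():
            if entry.assigned_gene and entry.gene_span:
                seen.setdefault(tuple(entry.gene_span), entry.assigned_gene)
        for (chrom, start, end), symbol in seen.items():
            targets.append((symbol, chrom, start, end))

    skipped = 0
    with open(path, "w", newline="\n") as fh:
        for label, chrom, start, end in targets:
            seq = _resolve_seq(fasta, chrom)
            if seq is None:
                skipped += 1
                continue
            # pyfaidx slices are 0-based half-open
            subseq = str(seq[start - 1:end]).upper()
            fh.write(f">{label}::{chrom}:{start}-{end}\n")
            for i in range(0, len(subseq), 70):
                fh.write(subseq[i:i + 70] + "\n")
    return path, skipped
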