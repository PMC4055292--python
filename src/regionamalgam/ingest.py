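"""Dataset ingestion and translation onto genomic coordinates.

Each of the K input files is delimited text with a header; a row carries
a gene name and/or a chromosome + start/stop span, plus any number of
passthrough value/metadata columns that are carried untouched into the
merged output.  Every entry is translated to coordinates either directly
(coordinates supplied), by forward name lookup against the gene library
(synonyms included), or stays in the unmapped report with a reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .library import (
    GeneLibrary,
    chrom_sort_key,
    lookup_by_interval,
    lookup_by_name,
    normalize_chrom,
    span_length,
)

__all__ = [
    "ColumnMap",
    "DatasetEntry",
    "Dataset",
    "AnnotatedEntry",
    "AnnotationPolicy",
    "UnmappedReport",
    "IngestError",
    "load_dataset",
    "annotate_dataset",
    "load_merged_output",
    "auto_column_map",
    "SENTINEL",
]

SENTINEL = "#regionamalgam"
FORMAT_VERSION = 1

# fixed columns of the merged Txt schema, in order; passthrough follows
TXT_COLUMNS = [
    "Chrom", "StartFlag", "StopFlag", "Start", "Stop", "EntityName",
    "DataType", "IsDefining", "DatasetId", "AssignedGene", "GeneIds",
    "GeneSpan", "Resolution", "Note",
]


class IngestError(ValueError):
    """Configuration or format problem with an input dataset file."""


@dataclass
class ColumnMap:
    """Which columns of a dataset file hold the entity name and/or span.

    At least a name column or a full (chrom, start, end) triple must be
    designated; every column not named here becomes passthrough.
    """

    name: str | None = None
    chrom: str | None = None
    start: str | None = None
    end: str | None = None
    delimiter: str | None = None

    def validate(self) -> None:
        triple = (self.chrom, self.start, self.end)
        if self.name is None and not all(triple):
            raise IngestError(
                "column map must designate a name column or a full "
                "chrom/start/end triple"
            )

    @property
    def mapped_columns(self) -> set[str]:
        return {c for c in (self.name, self.chrom, self.start, self.end) if c}


_NAME_ALIASES = {"gene", "symbol", "name", "gene_name", "genesymbol",
                 "gene_symbol", "entityname", "entity_name", "entity"}
_CHROM_ALIASES = {"chrom", "chromosome", "chr", "chrom_name"}
_START_ALIASES = {"start", "start_pos", "startpos", "chromstart", "begin"}
_END_ALIASES = {"end", "stop", "end_pos", "stoppos", "chromend"}


def auto_column_map(columns: list[str]) -> ColumnMap:
    """Guess the name/coordinate columns from common header spellings."""
    cmap = ColumnMap()
    for col in columns:
        low = col.strip().lower()
        if cmap.name is None and low in _NAME_ALIASES:
            cmap.name = col
        elif cmap.chrom is None and low in _CHROM_ALIASES:
            cmap.chrom = col
        elif cmap.start is None and low in _START_ALIASES:
            cmap.start = col
        elif cmap.end is None and low in _END_ALIASES:
            cmap.end = col
    if not (cmap.chrom and cmap.start and cmap.end):
        cmap.chrom = cmap.start = cmap.end = None
    cmap.validate()
    return cmap


@dataclass(eq=False)
class DatasetEntry:
    """One row of one uploaded file."""

    dataset_id: str
    data_type: str
    entity_name: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    passthrough: dict[str, str] = field(default_factory=dict)
    row_number: int = 0

    @property
    def has_coords(self) -> bool:
        return self.chrom is not None and self.start is not None and self.end is not None


@dataclass
class DatasetLoadReport:
    rows_in: int = 0
    loaded: int = 0
    malformed: int = 0
    duplicate_rows: int = 0
    malformed_rows: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class Dataset:
    """One uploaded file: ordered entries plus its platform tag."""

    dataset_id: str
    data_type: str
    entries: list[DatasetEntry]
    load_order: int = 0
    passthrough_columns: list[str] = field(default_factory=list)
    load_report: DatasetLoadReport = field(default_factory=DatasetLoadReport)
    # set when reconstructed from a previous merged output: annotation is
    # already final and must not be recomputed
    pre_annotated: bool = False
    annotated: list["AnnotatedEntry"] | None = None


@dataclass(eq=False)
class AnnotatedEntry:
    """A dataset entry with final genomic placement (or unmapped flag).

    ``resolution`` records the translation route:

    - ``given_coords``: the row supplied coordinates (the measured datum
      always wins for positioning; a resolvable name contributes the gene
      assignment, otherwise reverse annotation is attempted)
    - ``name_lookup``: coordinates adopted from the library span of a
      uniquely resolved gene name or synonym
    - ``reverse_annotation``: the row's name was present but unknown to
      the library; the coordinates placed it and an overlapping gene was
      recovered
    - ``key_only``: key-based merge member without genomic coordinates
    - ``unmapped``: no placement possible
    """

    entry: DatasetEntry
    resolved_chrom: str | None = None
    resolved_start: int | None = None
    resolved_end: int | None = None
    assigned_gene: str | None = None
    gene_identifiers: dict[str, str] = field(default_factory=dict)
    gene_span: tuple[str, int, int] | None = None
    resolution: str = "unmapped"
    ambiguity_note: str | None = None
    load_order: int = 0

    @property
    def dataset_id(self) -> str:
        return self.entry.dataset_id

    @property
    def data_type(self) -> str:
        return self.entry.data_type

    @property
    def entity_name(self) -> str | None:
        return self.entry.entity_name

    @property
    def passthrough(self) -> dict[str, str]:
        return self.entry.passthrough

    @property
    def length(self) -> int:
        return span_length(self.resolved_start, self.resolved_end)

    @property
    def label(self) -> str:
        """Display/tie-break label: name, else gene, else coordinate string."""
        if self.entry.entity_name:
            return self.entry.entity_name
        if self.assigned_gene:
            return self.assigned_gene
        if self.resolved_chrom is not None:
            return f"{self.resolved_chrom}:{self.resolved_start}-{self.resolved_end}"
        return ""


@dataclass
class AnnotationPolicy:
    """How ambiguous and gene-less entries are handled.

    ambiguous: ``reject`` (default) counts a multi-record name as
    unmapped, keeping the vocabulary deterministic; ``all_loci`` emits
    one annotated entry per matching locus.  require_gene: when True,
    coordinate-only entries that overlap no library gene are reported
    unmapped instead of standing alone.
    """

    ambiguous: str = "reject"
    require_gene: bool = False

    def __post_init__(self) -> None:
        if self.ambiguous not in ("reject", "all_loci"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguous!r}")


@dataclass
class UnmappedReport:
    """Entries that could not be placed, with per-dataset accounting."""

    entries: list[tuple[str, DatasetEntry, str]] = field(default_factory=list)

    REASONS = ("name_not_in_library", "ambiguous_name",
               "no_overlapping_gene_info", "malformed", "malformed-key")

    def add(self, dataset_id: str, entry: DatasetEntry, reason: str) -> None:
        if reason not in self.REASONS:
            raise ValueError(f"unknown unmapped reason {reason!r}")
        self.entries.append((dataset_id, entry, reason))

    def extend(self, other: "UnmappedReport") -> None:
        self.entries.extend(other.entries)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ds, _, _ in self.entries:
            out[ds] = out.get(ds, 0) + 1
        return out

    @property
    def total(self) -> int:
        return len(self.entries)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def load_dataset(
    path: str | Path,
    column_map: ColumnMap | None,
    dataset_id: str,
    data_type: str,
    load_order: int = 0,
) -> Dataset:
    """Parse one delimited annotation file into a :class:`Dataset`.

    Rows that designate neither a name nor a parseable coordinate triple
    are diverted to the load report as malformed; duplicates are kept
    (distinct probes may be identical rows) but counted.
    """
    path = Path(path)
    delim = (column_map.delimiter if column_map and column_map.delimiter
             else _sniff_delimiter(path))
    df = pd.read_csv(path, sep=delim, dtype=str, na_filter=False)
    df.columns = [c.strip() for c in df.columns]
    cmap = column_map or auto_column_map(list(df.columns))
    cmap.validate()
    for col in cmap.mapped_columns:
        if col not in df.columns:
            raise IngestError(
                f"dataset {dataset_id}: designated column '{col}' not in file"
            )

    passthrough_cols = [c for c in df.columns if c not in cmap.mapped_columns]
    report = DatasetLoadReport(rows_in=len(df))
    entries: list[DatasetEntry] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        name = str(row[cmap.name]).strip() if cmap.name else ""
        chrom = start = end = None
        coord_cells = (
            [str(row[c]).strip() for c in (cmap.chrom, cmap.start, cmap.end)]
            if cmap.chrom else ["", "", ""]
        )
        if any(coord_cells):
            # partially filled or unparseable coordinates are malformed,
            # even when a name is also present: the measured span is the
            # datum the row claims to carry
            try:
                if not all(coord_cells):
                    raise ValueError("incomplete coordinate triple")
                start = int(coord_cells[1])
                end = int(coord_cells[2])
                if start < 1 or end < start:
                    raise ValueError("inverted or non-positive span")
                chrom = normalize_chrom(coord_cells[0])
            except ValueError as exc:
                report.malformed += 1
                report.malformed_rows.append((i, str(exc)))
                continue
        if not name and chrom is None:
            report.malformed += 1
            report.malformed_rows.append((i, "no entity name and no coordinates"))
            continue
        entry = DatasetEntry(
            dataset_id=dataset_id,
            data_type=data_type,
            entity_name=name or None,
            chrom=chrom,
            start=start,
            end=end,
            passthrough={c: str(row[c]) for c in passthrough_cols},
            row_number=i,
        )
        key = (entry.entity_name, chrom, start, end,
               tuple(entry.passthrough.items()))
        if key in seen:
            report.duplicate_rows += 1
        seen.add(key)
        entries.append(entry)

    report.loaded = len(entries)
    return Dataset(
        dataset_id=dataset_id,
        data_type=data_type,
        entries=entries,
        load_order=load_order,
        passthrough_columns=passthrough_cols,
        load_report=report,
    )


def annotate_dataset(
    dataset: Dataset,
    library: GeneLibrary,
    policy: AnnotationPolicy | None = None,
) -> tuple[list[AnnotatedEntry], UnmappedReport]:
    """Translate every entry of a dataset onto genomic coordinates.

    Coordinates win over names for positioning; names still contribute
    the gene assignment (with a mismatch note when the library span
    disagrees).  Name-only entries adopt the library span of a unique
    match; ambiguous names follow the policy.  Coordinate entries whose
    name is absent or unknown are reverse-annotated against the library,
    the highest-overlap gene winning and the full overlap list kept in
    the ambiguity note.
    """
    policy = policy or AnnotationPolicy()
    if dataset.pre_annotated and dataset.annotated is not None:
        for a in dataset.annotated:
            a.load_order = dataset.load_order
        return list(dataset.annotated), UnmappedReport()

    annotated: list[AnnotatedEntry] = []
    unmapped = UnmappedReport()
    for entry in dataset.entries:
        matches = lookup_by_name(library, entry.entity_name) if entry.entity_name else []
        if entry.has_coords:
            ann = AnnotatedEntry(
                entry=entry,
                resolved_chrom=entry.chrom,
                resolved_start=entry.start,
                resolved_end=entry.end,
                resolution="given_coords",
                load_order=dataset.load_order,
            )
            notes = []
            if len(matches) == 1 or (matches and matches[0][1] == "canonical"
                                     and sum(1 for _, k in matches if k == "canonical") == 1):
                rec = matches[0][0]
                ann.assigned_gene = rec.symbol
                ann.gene_identifiers = dict(rec.identifiers)
                ann.gene_span = (rec.chrom, rec.start, rec.end)
                if (rec.chrom != entry.chrom or rec.start != entry.start
                        or rec.end != entry.end):
                    notes.append(
                        f"name/coords mismatch: library places {rec.symbol} at "
                        f"{rec.chrom}:{rec.start}-{rec.end}"
                    )
            else:
                if len(matches) > 1:
                    notes.append(
                        "ambiguous name: "
                        + ",".join(sorted({r.symbol for r, _ in matches}))
                    )
                hits = lookup_by_interval(
                    library, entry.chrom, entry.start, entry.end
                )
                if hits:
                    best, _ = hits[0]
                    ann.assigned_gene = best.symbol
                    ann.gene_identifiers = dict(best.identifiers)
                    ann.gene_span = (best.chrom, best.start, best.end)
                    notes.append(
                        "overlaps: "
                        + ",".join(f"{r.symbol}:{ov}" for r, ov in hits)
                    )
                    if entry.entity_name:
                        # name was present but did not resolve: placement
                        # by coordinates with overlap-recovered gene
                        ann.resolution = "reverse_annotation"
                elif policy.require_gene and not entry.entity_name:
                    unmapped.add(dataset.dataset_id, entry,
                                 "no_overlapping_gene_info")
                    continue
            ann.ambiguity_note = "; ".join(notes) or None
            annotated.append(ann)
        elif matches:
            distinct = list(dict.fromkeys(r for r, _ in matches))
            if len(distinct) > 1 and policy.ambiguous == "reject":
                unmapped.add(dataset.dataset_id, entry, "ambiguous_name")
                continue
            chosen = distinct if len(distinct) > 1 else distinct[:1]
            for rec in chosen:
                kind = next(k for r, k in matches if r is rec)
                note = None
                if len(distinct) > 1:
                    note = ("multi-locus name, all loci emitted: "
                            + ",".join(f"{r.chrom}:{r.start}-{r.end}" for r in distinct))
                elif kind == "synonym":
                    note = f"matched as synonym of {rec.symbol}"
                annotated.append(AnnotatedEntry(
                    entry=entry,
                    resolved_chrom=rec.chrom,
                    resolved_start=rec.start,
                    resolved_end=rec.end,
                    assigned_gene=rec.symbol,
                    gene_identifiers=dict(rec.identifiers),
                    gene_span=(rec.chrom, rec.start, rec.end),
                    resolution="name_lookup",
                    ambiguity_note=note,
                    load_order=dataset.load_order,
                ))
        else:
            unmapped.add(dataset.dataset_id, entry, "name_not_in_library")
    return annotated, unmapped


# ---------------------------------------------------------------------------
# round trip: reload a previously written merged Txt file as datasets

def _parse_sentinel(line: str) -> dict[str, str]:
    if not line.startswith(SENTINEL):
        raise IngestError("not a regionamalgam merged file")
    fields = {}
    for tok in line.rstrip("\n").split("\t")[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    if fields.get("format") != str(FORMAT_VERSION):
        raise IngestError("not a regionamalgam merged file")
    return fields


def is_merged_output(path: str | Path) -> bool:
    """True when the file carries the merged-output sentinel header."""
    try:
        with open(path) as fh:
            return fh.readline().startswith(SENTINEL + "\t")
    except OSError:
        return False


def load_merged_output(path: str | Path) -> list[Dataset]:
    """Reconstruct the original datasets from a merged Txt export.

    The sentinel block records each source dataset (id, data type,
    passthrough columns) in load order; entries come back pre-annotated
    with their original placement, gene assignment and resolution, so
    re-merging them with no additional inputs reproduces the map exactly.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise IngestError("not a regionamalgam merged file")
    _parse_sentinel(lines[0])

    ds_specs: list[tuple[str, str, list[str]]] = []
    body_start = 1
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#dataset\t"):
            parts = line.split("\t")
            cols = parts[3].split("|") if len(parts) > 3 and parts[3] else []
            ds_specs.append((parts[1], parts[2], cols))
        elif line.startswith("#"):
            continue
        else:
            body_start = i
            break
    header = lines[body_start].split("\t")
    idx = {c: j for j, c in enumerate(header)}
    for col in TXT_COLUMNS:
        if col not in idx:
            raise IngestError("not a regionamalgam merged file")

    datasets: dict[str, Dataset] = {}
    for order, (ds_id, dtype, cols) in enumerate(ds_specs):
        datasets[ds_id] = Dataset(
            dataset_id=ds_id, data_type=dtype, entries=[],
            load_order=order, passthrough_columns=list(cols),
            pre_annotated=True, annotated=[],
        )

    for row_number, line in enumerate(lines[body_start + 1:]):
        if not line:
            continue
        cells = line.split("\t")
        get = lambda c: cells[idx[c]] if idx[c] < len(cells) else ""
        ds_id = get("DatasetId")
        if ds_id not in datasets:
            raise IngestError(
                f"merged file row references unknown dataset {ds_id!r}"
            )
        ds = datasets[ds_id]
        name = get("EntityName") or None
        start = int(get("Start"))
        end = int(get("Stop"))
        chrom = get("Chrom")
        entry = DatasetEntry(
            dataset_id=ds_id,
            data_type=ds.data_type,
            entity_name=name,
            chrom=chrom,
            start=start,
            end=end,
            passthrough={c: get(c) if c in idx else ""
                         for c in ds.passthrough_columns},
            row_number=row_number,
        )
        gene_ids = {}
        if get("GeneIds"):
            for tok in get("GeneIds").split("|"):
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    gene_ids[k] = v
        gene_span = None
        if get("GeneSpan"):
            gchrom, gspan = get("GeneSpan").rsplit(":", 1)
            gs, ge = gspan.split("-")
            gene_span = (gchrom, int(gs), int(ge))
        resolution = get("Resolution")
        if resolution in ("name_lookup",):
            # name-only rows must round-trip as name-only entries
            entry.chrom = entry.start = entry.end = None
        ds.entries.append(entry)
        ds.annotated.append(AnnotatedEntry(
            entry=entry,
            resolved_chrom=chrom,
            resolved_start=start,
            resolved_end=end,
            assigned_gene=get("AssignedGene") or None,
            gene_identifiers=gene_ids,
            gene_span=gene_span,
            resolution=resolution,
            ambiguity_note=get("Note") or None,
            load_order=ds.load_order,
        ))

    out = [datasets[ds_id] for ds_id, _, _ in ds_specs]
    if not out or not any(d.entries for d in out):
        raise IngestError("merged file contains no data rows")
    return out
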