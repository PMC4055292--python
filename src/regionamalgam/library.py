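"""Local gene annotation repository: records, indices, and lookups.

The library stands in for locally mirrored NCBI/Ensembl/UCSC gene tables:
one row per gene locus with canonical symbol, synonyms, database
identifiers and a chromosomal span.  It supports forward translation
(name -> coordinates, synonyms included) and reverse annotation
(coordinates -> overlapping genes).

Coordinate convention: every public interface speaks 1-based *inclusive*
base-pair positions, the convention genome browsers display.  The
interval index internally stores half-open intervals (``intervaltree``
semantics) but that is never visible to callers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "GeneLibrary",
    "LibraryFormat",
    "LibraryLoadReport",
    "LibraryError",
    "load_gene_library",
    "lookup_by_name",
    "lookup_by_interval",
    "normalize_chrom",
    "chrom_sort_key",
    "span_length",
]


class LibraryError(ValueError):
    """Configuration or content problem with a gene-library file."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name for cross-database comparison.

    Strips a leading ``chr``/``Chr`` prefix, uppercases X/Y/MT and maps
    ``M`` to ``MT``.  The three public gene databases disagree on naming;
    all comparisons in this package happen on the normalized form.
    """
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    u = s.upper()
    if u in ("X", "Y", "MT"):
        return u
    if u == "M":
        return "MT"
    return s


def chrom_sort_key(chrom: str) -> tuple:
    """Genome-browser chromosome order: 1..22, X, Y, MT, then others."""
    s = normalize_chrom(chrom)
    if s.isdigit():
        return (0, int(s), "")
    special = {"X": 0, "Y": 1, "MT": 2}
    if s in special:
        return (1, special[s], "")
    return (2, 0, s)


def span_length(start: int, end: int) -> int:
    """Inclusive span length in base pairs."""
    return end - start + 1


@dataclass(eq=False)
class GeneRecord:
    """One gene locus: symbol, synonyms, identifiers and chromosomal span.

    A gene annotated at several loci is stored as several records sharing
    the symbol; name lookup returns all of them.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    synonyms: frozenset[str] = frozenset()
    identifiers: Mapping[str, str] = field(default_factory=dict)
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol or not str(self.symbol).strip():
            raise LibraryError("gene record requires a non-empty symbol")
        self.symbol = str(self.symbol).strip()
        self.chrom = normalize_chrom(self.chrom)
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 1 or self.end < self.start:
            raise LibraryError(
                f"invalid span {self.start}-{self.end} for {self.symbol}"
            )
        # a symbol never doubles as its own synonym
        self.synonyms = frozenset(
            s.strip()
            for s in self.synonyms
            if s.strip() and s.strip().upper() != self.symbol.upper()
        )
        if self.strand not in ("+", "-", "unknown"):
            self.strand = "unknown"

    @property
    def length(self) -> int:
        return span_length(self.start, self.end)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneRecord({self.symbol} {self.chrom}:{self.start}-{self.end})"


@dataclass
class LibraryLoadReport:
    rows_in: int = 0
    loaded: int = 0
    skipped_malformed: int = 0
    collapsed_duplicates: int = 0


@dataclass
class LibraryFormat:
    """Column-name mapping for a delimited gene-library file.

    Canonical column names are remappable; ``synonyms`` cells hold a
    separator-joined list (default ``|``, the NCBI gene_info convention).
    Identifier columns are optional, keyed by database name.
    """

    symbol: str = "symbol"
    synonyms: str | None = "synonyms"
    chrom: str = "chrom"
    start: str = "start"
    end: str = "end"
    strand: str | None = "strand"
    identifiers: Mapping[str, str] = field(
        default_factory=lambda: {
            "ncbi": "ncbi_id",
            "ensembl": "ensembl_id",
            "ucsc": "ucsc_id",
        }
    )
    synonym_sep: str = "|"
    delimiter: str | None = None  # None -> sniff tab/comma


class GeneLibrary:
    """Indexed collection of :class:`GeneRecord`.

    ``name_index`` maps uppercased symbol-or-synonym to the set of records
    carrying it; ``interval_index`` answers per-chromosome overlap queries.
    """

    def __init__(self, records: Iterable[GeneRecord], assembly_label: str = ""):
        self.records: list[GeneRecord] = list(records)
        if not self.records:
            raise LibraryError("no usable gene records")
        self.assembly_label = assembly_label
        self.load_report = LibraryLoadReport()
        self.name_index: dict[str, set[GeneRecord]] = {}
        self.interval_index: dict[str, IntervalTree] = {}
        for rec in self.records:
            self.name_index.setdefault(rec.symbol.upper(), set()).add(rec)
            for syn in rec.synonyms:
                self.name_index.setdefault(syn.upper(), set()).add(rec)
            tree = self.interval_index.setdefault(rec.chrom, IntervalTree())
            # inclusive [start, end] -> half-open [start, end + 1)
            tree.addi(rec.start, rec.end + 1, rec)

    def __len__(self) -> int:
        return len(self.records)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def load_gene_library(
    path: str | Path,
    format_spec: LibraryFormat | None = None,
    assembly_label: str = "",
) -> GeneLibrary:
    """Load and index a delimited gene-library file.

    Rows with unparseable or inverted coordinates are skipped and counted
    in the load report.  Duplicate (symbol, chrom, start, end) rows are
    collapsed into one record with merged synonyms and identifiers.
    """
    fmt = format_spec or LibraryFormat()
    path = Path(path)
    delim = fmt.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype=str, na_filter=False)
    df.columns = [c.strip() for c in df.columns]

    required = {"symbol": fmt.symbol, "chrom": fmt.chrom,
                "start": fmt.start, "end": fmt.end}
    for role, col in required.items():
        if col not in df.columns:
            raise LibraryError(
                f"library file {path.name} is missing required column "
                f"'{col}' (role: {role})"
            )

    report = LibraryLoadReport(rows_in=len(df))
    collapsed: dict[tuple, GeneRecord] = {}
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            start = int(str(row[fmt.start]).strip())
            end = int(str(row[fmt.end]).strip())
            syns: frozenset[str] = frozenset()
            if fmt.synonyms and fmt.synonyms in df.columns:
                cell = str(row[fmt.synonyms]).strip()
                if cell:
                    syns = frozenset(
                        s.strip() for s in cell.split(fmt.synonym_sep) if s.strip()
                    )
            idents = {}
            for db, col in fmt.identifiers.items():
                if col in df.columns and str(row[col]).strip():
                    idents[db] = str(row[col]).strip()
            strand = "unknown"
            if fmt.strand and fmt.strand in df.columns:
                s = str(row[fmt.strand]).strip()
                if s in ("+", "-"):
                    strand = s
            rec = GeneRecord(
                symbol=str(row[fmt.symbol]),
                chrom=str(row[fmt.chrom]),
                start=start,
                end=end,
                synonyms=syns,
                identifiers=idents,
                strand=strand,
            )
        except (ValueError, LibraryError):
            report.skipped_malformed += 1
            continue
        key = (rec.symbol.upper(), rec.chrom, rec.start, rec.end)
        if key in collapsed:
            old = collapsed[key]
            merged_ids = dict(old.identifiers)
            merged_ids.update(rec.identifiers)
            collapsed[key] = GeneRecord(
                symbol=old.symbol,
                chrom=old.chrom,
                start=old.start,
                end=old.end,
                synonyms=old.synonyms | rec.synonyms,
                identifiers=merged_ids,
                strand=old.strand if old.strand != "unknown" else rec.strand,
            )
            report.collapsed_duplicates += 1
        else:
            collapsed[key] = rec

    report.loaded = len(collapsed)
    lib = GeneLibrary(collapsed.values(), assembly_label=assembly_label)
    lib.load_report = report
    return lib


def lookup_by_name(
    library: GeneLibrary, name: str
) -> list[tuple[GeneRecord, str]]:
    """Case-insensitive forward lookup: canonical matches before synonym.

    No match is an empty result, not an error.  Multi-locus names return
    every matching record; the caller applies its ambiguity policy.
    """
    u = str(name).strip().upper()
    if not u:
        return []
    recs = library.name_index.get(u, set())
    canonical = sorted(
        (r for r in recs if r.symbol.upper() == u),
        key=lambda r: (chrom_sort_key(r.chrom), r.start, r.symbol),
    )
    synonym = sorted(
        (r for r in recs if r.symbol.upper() != u),
        key=lambda r: (chrom_sort_key(r.chrom), r.start, r.symbol),
    )
    return [(r, "canonical") for r in canonical] + [(r, "synonym") for r in synonym]


def lookup_by_interval(
    library: GeneLibrary, chrom: str, start: int, end: int
) -> list[tuple[GeneRecord, int]]:
    """Reverse annotation: every gene intersecting [start, end] by >= 1 bp.

    Returns (record, overlap_bp) sorted by descending overlap, ties broken
    by ascending symbol.  An unknown chromosome yields an empty list.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    tree = library.interval_index.get(normalize_chrom(chrom))
    if tree is None:
        return []
    hits = []
    for iv in tree.overlap(start, end + 1):
        rec: GeneRecord = iv.data
        ov = min(rec.end, end) - max(rec.start, start) + 1
        if ov >= 1:
            hits.append((rec, ov))
    hits.sort(key=lambda t: (-t[1], t[0].symbol, t[0].start))
    return hits
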