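"""Construction of the genome-wide vocabulary of regional units.

A regional unit is a maximal envelope of transitively overlapping
annotated entries across all datasets: per chromosome, entries are
partitioned into connected components under "spans share >= 1 bp"
(inclusive coordinates; abutting intervals do NOT merge), each component
becoming one unit bounded by StartFlag/StopFlag.  The widest member is
the unit's defining entity and its dataset the unit's origin; every
other member is a subregion.  All datasets contribute on equal terms —
no dataset outranks another except in deterministic tie-breaks.

The sweep is a single left-to-right pass tracking the running maximum
end, O(n log n) per chromosome from the sort; the quadratic closure
exists only as the independent test oracle in :mod:`.fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .ingest import AnnotatedEntry, Dataset, IngestError, UnmappedReport
from .library import chrom_sort_key, normalize_chrom, span_length

__all__ = [
    "RegionalUnit",
    "MergedMap",
    "MergeError",
    "build_regional_units",
    "merge_by_key",
    "defining_sort_key",
    "validate_merged_map",
    "maps_equal",
]


class MergeError(ValueError):
    pass


@dataclass(eq=False)
class RegionalUnit:
    """One vocabulary element: envelope span plus its member entries.

    ``key`` is set only in key-based merge mode, where the unit is a
    shared identifier rather than a genomic interval; such units carry
    coordinates only when all members agree on the chromosome.
    """

    chrom: str | None
    start_flag: int | None
    stop_flag: int | None
    defining_entry: AnnotatedEntry
    subregions: list[AnnotatedEntry] = field(default_factory=list)
    key: str | None = None

    @property
    def origin_dataset(self) -> str:
        return self.defining_entry.dataset_id

    @property
    def members(self) -> list[AnnotatedEntry]:
        """Defining entry first, then subregions in their sorted order."""
        return [self.defining_entry, *self.subregions]

    @property
    def n_entries(self) -> int:
        return 1 + len(self.subregions)

    @property
    def span_label(self) -> str:
        if self.chrom is None:
            return self.key or ""
        return f"{self.chrom}:{self.start_flag}-{self.stop_flag}"


@dataclass
class MergedMap:
    """The complete ordered vocabulary plus the unmapped-entry report."""

    units: list[RegionalUnit]
    unmapped: UnmappedReport = field(default_factory=UnmappedReport)
    provenance: dict = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return sum(u.n_entries for u in self.units)

    def iter_entries(self):
        for unit in self.units:
            for member in unit.members:
                yield unit, member


def defining_sort_key(entry: AnnotatedEntry) -> tuple:
    """Tie-break chain for the defining entity: widest span first, then
    lower dataset load order, then lexicographically smaller label, then
    smaller start.  Fully deterministic."""
    return (-entry.length, entry.load_order, entry.label, entry.resolved_start)


def _subregion_sort_key(entry: AnnotatedEntry) -> tuple:
    return (entry.resolved_start, entry.resolved_end, entry.load_order,
            entry.label)


def build_regional_units(
    datasets: Sequence[tuple[Dataset, Sequence[AnnotatedEntry]]],
    unmapped: UnmappedReport | None = None,
    provenance: dict | None = None,
) -> MergedMap:
    """Partition all annotated entries into non-overlapping regional units.

    Entries still flagged unmapped are ignored (they belong in the
    unmapped report, not the vocabulary).  Raises when no mapped entry
    exists at all.
    """
    if not datasets:
        raise MergeError("empty vocabulary: no datasets supplied")
    by_chrom: dict[str, list[AnnotatedEntry]] = {}
    for _, annotated in datasets:
        for entry in annotated:
            if entry.resolution == "unmapped" or entry.resolved_chrom is None:
                continue
            by_chrom.setdefault(normalize_chrom(entry.resolved_chrom), []).append(entry)
    if not by_chrom:
        raise MergeError("empty vocabulary: no mapped entries")

    units: list[RegionalUnit] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        entries = sorted(by_chrom[chrom],
                         key=lambda e: (e.resolved_start, e.resolved_end,
                                        e.load_order, e.label))
        component: list[AnnotatedEntry] = []
        max_end = None
        for entry in entries:
            if component and entry.resolved_start > max_end:
                units.append(_make_unit(chrom, component))
                component = []
                max_end = None
            component.append(entry)
            max_end = entry.resolved_end if max_end is None else max(
                max_end, entry.resolved_end)
        if component:
            units.append(_make_unit(chrom, component))

    return MergedMap(units=units,
                     unmapped=unmapped or UnmappedReport(),
                     provenance=dict(provenance or {}))


def _make_unit(chrom: str, members: list[AnnotatedEntry]) -> RegionalUnit:
    defining = min(members, key=defining_sort_key)
    subs = sorted((m for m in members if m is not defining),
                  key=_subregion_sort_key)
    return RegionalUnit(
        chrom=chrom,
        start_flag=min(m.resolved_start for m in members),
        stop_flag=max(m.resolved_end for m in members),
        defining_entry=defining,
        subregions=subs,
    )


def merge_by_key(
    datasets: Sequence[Dataset],
    key_column: str,
    unmapped: UnmappedReport | None = None,
    provenance: dict | None = None,
) -> MergedMap:
    """Alternative merge mode: the unit is a shared identifier column.

    Entries with an identical (case-insensitive) key value form one unit;
    keys present in only one dataset still form singleton units.  The
    defining entry is chosen by load order, then label, then start (span
    length plays no role).  Units carry an envelope span only when every
    member has coordinates on one chromosome; mixed or absent coordinates
    leave the unit coordinate-free (excluded from BED export).
    """
    if not datasets:
        raise MergeError("empty vocabulary: no datasets supplied")
    use_name = key_column.strip().lower() in (
        "entityname", "entity_name", "name", "gene")
    for ds in datasets:
        if not use_name and key_column not in ds.passthrough_columns:
            raise MergeError(
                f"key column '{key_column}' missing from dataset "
                f"{ds.dataset_id}"
            )

    report = unmapped or UnmappedReport()
    groups: dict[str, list[AnnotatedEntry]] = {}
    display: dict[str, str] = {}
    for ds in datasets:
        pool = ds.annotated if ds.pre_annotated and ds.annotated else None
        source = pool if pool is not None else ds.entries
        for item in source:
            entry = item.entry if isinstance(item, AnnotatedEntry) else item
            key = (entry.entity_name if use_name
                   else entry.passthrough.get(key_column, ""))
            key = (key or "").strip()
            if not key:
                report.add(ds.dataset_id, entry, "malformed-key")
                continue
            if isinstance(item, AnnotatedEntry):
                ann = item
            elif entry.has_coords:
                ann = AnnotatedEntry(
                    entry=entry, resolved_chrom=entry.chrom,
                    resolved_start=entry.start, resolved_end=entry.end,
                    resolution="given_coords", load_order=ds.load_order)
            else:
                ann = AnnotatedEntry(entry=entry, resolution="key_only",
                                     load_order=ds.load_order)
            groups.setdefault(key.upper(), []).append(ann)
            display.setdefault(key.upper(), key)

    if not groups:
        raise MergeError("empty vocabulary: no keyed entries")

    units = []
    for ukey in sorted(groups):
        members = groups[ukey]
        defining = min(members, key=lambda e: (e.load_order, e.label,
                                               e.resolved_start
                                               if e.resolved_start is not None
                                               else float("inf")))
        subs = sorted(
            (m for m in members if m is not defining),
            key=lambda e: (e.resolved_start if e.resolved_start is not None
                           else float("inf"),
                           e.resolved_end if e.resolved_end is not None
                           else float("inf"),
                           e.load_order, e.label))
        chroms = {m.resolved_chrom for m in members}
        if len(chroms) == 1 and None not in chroms:
            chrom = chroms.pop()
            unit = RegionalUnit(
                chrom=chrom,
                start_flag=min(m.resolved_start for m in members),
                stop_flag=max(m.resolved_end for m in members),
                defining_entry=defining, subregions=subs,
                key=display[ukey])
        else:
            unit = RegionalUnit(chrom=None, start_flag=None, stop_flag=None,
                                defining_entry=defining, subregions=subs,
                                key=display[ukey])
        units.append(unit)

    prov = dict(provenance or {})
    prov.setdefault("merge_mode", "key")
    prov.setdefault("key_column", key_column)
    return MergedMap(units=units, unmapped=report, provenance=prov)


# ---------------------------------------------------------------------------
# independent validation and comparison helpers

def validate_merged_map(m: MergedMap) -> None:
    """Re-scan a map and assert its structural invariants.

    Deliberately independent of the builders' own bookkeeping: envelopes,
    widest-member property, pairwise non-overlap and connectivity are all
    recomputed from the member entries.  Raises AssertionError on the
    first violation.
    """
    prev: dict[str, RegionalUnit] = {}
    for unit in m.units:
        members = unit.members
        assert members, "unit without members"
        if unit.chrom is None:
            continue  # coordinate-free key-mode unit
        starts = [e.resolved_start for e in members]
        ends = [e.resolved_end for e in members]
        assert unit.start_flag == min(starts), "envelope start violated"
        assert unit.stop_flag == max(ends), "envelope stop violated"
        dlen = unit.defining_entry.length
        assert all(dlen >= e.length for e in members), \
            "defining entry is not the widest member"
        for e in members:
            assert normalize_chrom(e.resolved_chrom) == unit.chrom
        # connectivity: sweeping the sorted member spans must never gap
        spans = sorted(zip(starts, ends))
        reach = spans[0][1]
        for s, e in spans[1:]:
            assert s <= reach, "unit members are not transitively connected"
            reach = max(reach, e)
        if unit.chrom in prev:
            p = prev[unit.chrom]
            assert unit.start_flag > p.stop_flag, \
                "units on one chromosome overlap or touch out of order"
        prev[unit.chrom] = unit
    # chromosome-major ordering of units with coordinates
    keyed = [(chrom_sort_key(u.chrom), u.start_flag)
             for u in m.units if u.chrom is not None]
    assert keyed == sorted(keyed), "units out of genome order"


def _member_fields(e: AnnotatedEntry) -> tuple:
    return (e.dataset_id, e.data_type, e.entity_name,
            e.resolved_chrom, e.resolved_start, e.resolved_end,
            e.resolution, e.assigned_gene,
            tuple(sorted(e.passthrough.items())))


def maps_equal(a: MergedMap, b: MergedMap) -> bool:
    """Structural equality of two maps: spans, membership, member fields
    (dataset, name, type, placement, resolution, gene assignment,
    passthrough) and defining entities.  Free-text audit notes are not
    compared."""
    if len(a.units) != len(b.units):
        return False
    for ua, ub in zip(a.units, b.units):
        if (ua.chrom, ua.start_flag, ua.stop_flag, ua.key) != \
           (ub.chrom, ub.start_flag, ub.stop_flag, ub.key):
            return False
        if _member_fields(ua.defining_entry) != _member_fields(ub.defining_entry):
            return False
        if len(ua.subregions) != len(ub.subregions):
            return False
        for sa, sb in zip(ua.subregions, ub.subregions):
            if _member_fields(sa) != _member_fields(sb):
                return False
    return True
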