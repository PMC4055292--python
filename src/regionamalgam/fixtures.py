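"""Synthetic gene libraries and annotation tracks with planted ground truth.

The generator emulates the study setting — one local gene library plus K
platform files (expression, RNA-Seq, CNV, methylation) whose rows carry
either a gene name/synonym or a chromosomal span plus passthrough value
columns — at desk scale, with the true regional-unit vocabulary known by
construction: units are planted first and every entry is drawn inside
one planted unit, with the first entry of each occupied unit spanning it
entirely (so each unit is connected and its envelope is the planted
span).  Ground truth is therefore independent of both the production
sweep-line and the quadratic oracle below.

Also hosts :func:`oracle_regional_units`, a brute-force overlap-closure
construction by repeated pairwise merging over explicit base-pair sets,
sharing no code with the sweep-line builder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import AnnotatedEntry, DatasetEntry, UnmappedReport
from .library import chrom_sort_key
from .merge import MergedMap, RegionalUnit, validate_merged_map

__all__ = [
    "FixtureSpec",
    "FixtureResult",
    "generate_fixture",
    "oracle_regional_units",
    "random_annotated_entries",
]

_DATA_TYPES = ("microarray-expr", "rnaseq", "cnv", "methylation")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a small three-platform merge: two chromosomes with
    four planted units and eight genes each, K = 3 datasets of 20/15/12
    entries, half supplied as names and half as coordinate spans, 10 % of
    rows deliberately unmappable (bogus names), of which half are
    recoverable through a fallback library.  Same seed, same fixture,
    byte for byte.
    """

    n_chromosomes: int = 2
    units_per_chrom: int = 4
    n_genes_per_chrom: int = 8
    dataset_entries: tuple[int, ...] = (20, 15, 12)
    name_fraction: float = 0.5
    synonym_fraction: float = 0.3
    unmappable_fraction: float = 0.1
    fallback_resolvable_fraction: float = 0.5
    min_gap: int = 50
    max_gap: int = 500
    min_unit_len: int = 300
    max_unit_len: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for frac in (self.name_fraction, self.synonym_fraction,
                     self.unmappable_fraction,
                     self.fallback_resolvable_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fixture fractions must lie in [0, 1]")
        if min(self.n_chromosomes, self.units_per_chrom,
               self.n_genes_per_chrom) < 1:
            raise ValueError("fixture counts must be >= 1")
        if not self.dataset_entries or min(self.dataset_entries) < 1:
            raise ValueError("every dataset needs >= 1 entries")
        n_units = self.n_chromosomes * self.units_per_chrom
        if sum(self.dataset_entries) < n_units:
            raise ValueError("not enough entries to occupy every planted unit")
        if self.n_genes_per_chrom < self.units_per_chrom:
            raise ValueError("need at least one gene per planted unit")


@dataclass
class _PlantedGene:
    symbol: str
    chrom: str
    start: int
    end: int
    synonyms: list[str]
    identifiers: dict[str, str]


@dataclass
class _PlantedUnit:
    chrom: str
    start: int
    end: int
    genes: list[_PlantedGene] = field(default_factory=list)
    members: list[AnnotatedEntry] = field(default_factory=list)


@dataclass
class FixtureResult:
    library_path: Path
    dataset_paths: list[tuple[Path, str, str]]  # (path, dataset_id, data_type)
    fallback_library_path: Path | None
    expected_map: MergedMap
    planted_unmappable: dict[str, int]
    planted_fallback_resolvable: int
    spec: FixtureSpec


def _pick_defining(members: Sequence[AnnotatedEntry]) -> AnnotatedEntry:
    # explicit comparison chain, written independently of the merge module
    best = members[0]
    for cand in members[1:]:
        bl = best.resolved_end - best.resolved_start + 1
        cl = cand.resolved_end - cand.resolved_start + 1
        if cl != bl:
            if cl > bl:
                best = cand
        elif cand.load_order != best.load_order:
            if cand.load_order < best.load_order:
                best = cand
        elif cand.label != best.label:
            if cand.label < best.label:
                best = cand
        elif cand.resolved_start < best.resolved_start:
            best = cand
    return best


def _order_subregions(members: Sequence[AnnotatedEntry],
                      defining: AnnotatedEntry) -> list[AnnotatedEntry]:
    return sorted((m for m in members if m is not defining),
                  key=lambda e: (e.resolved_start, e.resolved_end,
                                 e.load_order, e.label))


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureResult:
    """Write library + K dataset files and return the planted truth.

    The expected map is assembled constructively from the planted units
    and the entries drawn into them, then checked against the structural
    map invariants before being returned.
    """
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # --- plant units and genes -------------------------------------------
    units: list[_PlantedUnit] = []
    genes: list[_PlantedGene] = []
    gene_counter = 0
    for ci in range(spec.n_chromosomes):
        chrom = str(ci + 1)
        crng = np.random.default_rng([spec.seed, ci])
        cursor = 1
        chrom_units: list[_PlantedUnit] = []
        for _ in range(spec.units_per_chrom):
            gap = int(crng.integers(spec.min_gap, spec.max_gap + 1))
            ulen = int(crng.integers(spec.min_unit_len, spec.max_unit_len + 1))
            start = cursor + gap
            unit = _PlantedUnit(chrom=chrom, start=start, end=start + ulen - 1)
            chrom_units.append(unit)
            cursor = unit.end + 1
        for g in range(spec.n_genes_per_chrom):
            unit = chrom_units[g % spec.units_per_chrom]
            gene_counter += 1
            if not unit.genes:
                gstart, gend = unit.start, unit.end  # first gene spans the unit
            else:
                gstart = int(crng.integers(unit.start, unit.end))
                gend = int(crng.integers(gstart, unit.end + 1))
            symbol = f"G{chrom}U{chrom_units.index(unit)}N{len(unit.genes)}"
            syns = []
            if crng.random() < spec.synonym_fraction:
                syns.append(f"SYN{symbol}")
            gene = _PlantedGene(
                symbol=symbol, chrom=chrom, start=gstart, end=gend,
                synonyms=syns,
                identifiers={"ncbi": str(10000 + gene_counter),
                             "ensembl": f"ENSG{gene_counter:011d}"},
            )
            unit.genes.append(gene)
            genes.append(gene)
        units.extend(chrom_units)

    # --- draw dataset rows ------------------------------------------------
    n_datasets = len(spec.dataset_entries)
    dataset_rows: list[list[dict]] = [[] for _ in range(n_datasets)]
    planted_unmappable: dict[str, int] = {}
    bogus_names: list[str] = []

    # anchors first: unit u goes to dataset u mod K, guaranteeing every
    # planted unit is occupied and its first entry spans it fully
    anchor_of: dict[int, int] = {}
    for ui, unit in enumerate(units):
        anchor_of[ui] = ui % n_datasets

    for k, n_entries in enumerate(spec.dataset_entries):
        ds_id = f"ds{k + 1}"
        planted_unmappable[ds_id] = 0
        my_units = [ui for ui, owner in anchor_of.items() if owner == k]
        for ui in my_units:
            unit = units[ui]
            if rng.random() < spec.name_fraction:
                gene = unit.genes[0]  # spans the whole unit
                name = gene.symbol
                if gene.synonyms and rng.random() < spec.synonym_fraction:
                    name = gene.synonyms[0]
                dataset_rows[k].append({"kind": "name", "name": name,
                                        "unit": ui, "gene": gene})
            else:
                dataset_rows[k].append({"kind": "coords", "unit": ui,
                                        "chrom": unit.chrom,
                                        "start": unit.start, "end": unit.end})
        for i in range(n_entries - len(my_units)):
            if rng.random() < spec.unmappable_fraction:
                bogus = f"BOGUS{k + 1}X{i}"
                bogus_names.append(bogus)
                planted_unmappable[ds_id] += 1
                dataset_rows[k].append({"kind": "bogus", "name": bogus})
                continue
            ui = int(rng.integers(0, len(units)))
            unit = units[ui]
            if unit.genes and rng.random() < spec.name_fraction:
                gene = unit.genes[int(rng.integers(0, len(unit.genes)))]
                name = gene.symbol
                if gene.synonyms and rng.random() < spec.synonym_fraction:
                    name = gene.synonyms[0]
                dataset_rows[k].append({"kind": "name", "name": name,
                                        "unit": ui, "gene": gene})
            else:
                s = int(rng.integers(unit.start, unit.end + 1))
                e = int(rng.integers(s, unit.end + 1))
                dataset_rows[k].append({"kind": "coords", "unit": ui,
                                        "chrom": unit.chrom,
                                        "start": s, "end": e})

    # --- write files ------------------------------------------------------
    library_path = outdir / "library.tsv"
    with open(library_path, "w", newline="\n") as fh:
        fh.write("symbol\tsynonyms\tchrom\tstart\tend\tstrand\tncbi_id\tensembl_id\n")
        for gene in genes:
            fh.write("\t".join([
                gene.symbol, "|".join(gene.synonyms), gene.chrom,
                str(gene.start), str(gene.end), "+",
                gene.identifiers["ncbi"], gene.identifiers["ensembl"],
            ]) + "\n")

    dataset_paths: list[tuple[Path, str, str]] = []
    for k, rows in enumerate(dataset_rows):
        ds_id = f"ds{k + 1}"
        dtype = _DATA_TYPES[k % len(_DATA_TYPES)]
        path = outdir / f"{ds_id}.tsv"
        extra = ["Score"] if k == 0 else []
        with open(path, "w", newline="\n") as fh:
            fh.write("\t".join(["Gene", "Chrom", "Start", "End", "Value"]
                               + extra) + "\n")
            for i, row in enumerate(rows):
                cells = [
                    row.get("name", ""),
                    f"chr{row['chrom']}" if row["kind"] == "coords" else "",
                    str(row["start"]) if row["kind"] == "coords" else "",
                    str(row["end"]) if row["kind"] == "coords" else "",
                    f"v{k + 1}.{i}",
                ] + ([f"s{i}"] if extra else [])
                fh.write("\t".join(cells) + "\n")
        dataset_paths.append((path, ds_id, dtype))

    # --- fallback library for a subset of the bogus names -----------------
    n_resolvable = math.ceil(
        len(bogus_names) * spec.fallback_resolvable_fraction)
    fallback_path = None
    if n_resolvable:
        fallback_path = outdir / "fallback_library.tsv"
        tail = max(u.end for u in units) + 10_000
        with open(fallback_path, "w", newline="\n") as fh:
            fh.write("symbol\tsynonyms\tchrom\tstart\tend\n")
            for j, name in enumerate(bogus_names[:n_resolvable]):
                s = tail + j * 2_000
                fh.write(f"{name}\t\t{units[0].chrom}\t{s}\t{s + 499}\n")

    # --- assemble the expected map constructively -------------------------
    for k, rows in enumerate(dataset_rows):
        ds_id = f"ds{k + 1}"
        dtype = _DATA_TYPES[k % len(_DATA_TYPES)]
        extra = ["Score"] if k == 0 else []
        for i, row in enumerate(rows):
            if row["kind"] == "bogus":
                continue
            passthrough = {"Value": f"v{k + 1}.{i}"}
            if extra:
                passthrough["Score"] = f"s{i}"
            unit = units[row["unit"]]
            if row["kind"] == "name":
                gene: _PlantedGene = row["gene"]
                entry = DatasetEntry(
                    dataset_id=ds_id, data_type=dtype,
                    entity_name=row["name"], passthrough=passthrough,
                    row_number=i)
                ann = AnnotatedEntry(
                    entry=entry, resolved_chrom=gene.chrom,
                    resolved_start=gene.start, resolved_end=gene.end,
                    assigned_gene=gene.symbol,
                    gene_identifiers=dict(gene.identifiers),
                    gene_span=(gene.chrom, gene.start, gene.end),
                    resolution="name_lookup", load_order=k)
            else:
                entry = DatasetEntry(
                    dataset_id=ds_id, data_type=dtype, entity_name=None,
                    chrom=row["chrom"], start=row["start"], end=row["end"],
                    passthrough=passthrough, row_number=i)
                best = None
                best_ov = 0
                for gene in unit.genes:
                    ov = (min(gene.end, row["end"])
                          - max(gene.start, row["start"]) + 1)
                    if ov >= 1 and (best is None or ov > best_ov
                                    or (ov == best_ov
                                        and gene.symbol < best.symbol)):
                        best, best_ov = gene, ov
                ann = AnnotatedEntry(
                    entry=entry, resolved_chrom=row["chrom"],
                    resolved_start=row["start"], resolved_end=row["end"],
                    assigned_gene=best.symbol if best else None,
                    gene_identifiers=dict(best.identifiers) if best else {},
                    gene_span=((best.chrom, best.start, best.end)
                               if best else None),
                    resolution="given_coords", load_order=k)
            unit.members.append(ann)

    expected_units = []
    for unit in sorted(units, key=lambda u: (chrom_sort_key(u.chrom), u.start)):
        if not unit.members:
            continue
        defining = _pick_defining(unit.members)
        expected_units.append(RegionalUnit(
            chrom=unit.chrom,
            start_flag=min(m.resolved_start for m in unit.members),
            stop_flag=max(m.resolved_end for m in unit.members),
            defining_entry=defining,
            subregions=_order_subregions(unit.members, defining),
        ))
    expected = MergedMap(units=expected_units)
    validate_merged_map(expected)

    return FixtureResult(
        library_path=library_path,
        dataset_paths=dataset_paths,
        fallback_library_path=fallback_path,
        expected_map=expected,
        planted_unmappable=planted_unmappable,
        planted_fallback_resolvable=n_resolvable,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# brute-force oracle

def oracle_regional_units(entries: Sequence[AnnotatedEntry]) -> MergedMap:
    """Overlap-closure partition by repeated pairwise merging (quadratic).

    Components are merged whenever their explicit base-pair sets
    intersect, until fixpoint; envelopes, defining entities and
    subregion order are then recomputed by exhaustive comparison.  Meant
    for small instances (couple hundred entries) as the independent
    check on the sweep-line builder.
    """
    mapped = [e for e in entries
              if e.resolution != "unmapped" and e.resolved_chrom is not None]
    comps: list[list[int]] = [[i] for i in range(len(mapped))]
    bpsets = [
        {(mapped[i].resolved_chrom, p)
         for p in range(mapped[i].resolved_start, mapped[i].resolved_end + 1)}
        for i in range(len(mapped))
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(comps)):
            if comps[i] is None:
                continue
            for j in range(i + 1, len(comps)):
                if comps[j] is None:
                    continue
                if bpsets[i] & bpsets[j]:
                    comps[i] = comps[i] + comps[j]
                    bpsets[i] |= bpsets[j]
                    comps[j] = None
                    bpsets[j] = set()
                    changed = True
    units = []
    for comp in comps:
        if comp is None:
            continue
        members = [mapped[i] for i in sorted(comp)]
        defining = _pick_defining(members)
        units.append(RegionalUnit(
            chrom=members[0].resolved_chrom,
            start_flag=min(m.resolved_start for m in members),
            stop_flag=max(m.resolved_end for m in members),
            defining_entry=defining,
            subregions=_order_subregions(members, defining),
        ))
    units.sort(key=lambda u: (chrom_sort_key(u.chrom), u.start_flag))
    return MergedMap(units=units)


def random_annotated_entries(
    rng: np.random.Generator,
    max_intervals: int = 60,
    max_datasets: int = 3,
    coord_space: int = 10_000,
    max_len: int = 400,
) -> list[AnnotatedEntry]:
    """Random coordinate-resolved entries for oracle-equivalence checks."""
    n_datasets = int(rng.integers(1, max_datasets + 1))
    n_total = int(rng.integers(1, max_intervals + 1))
    chroms = ["1", "2", "X"][: int(rng.integers(1, 4))]
    out = []
    for i in range(n_total):
        k = int(rng.integers(0, n_datasets))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, coord_space))
        length = int(rng.integers(1, max_len + 1))
        end = min(start + length - 1, coord_space)
        entry = DatasetEntry(
            dataset_id=f"ds{k + 1}", data_type="synthetic",
            entity_name=f"E{k + 1}_{i}", chrom=chrom, start=start, end=end,
            passthrough={"Value": str(i)}, row_number=i)
        out.append(AnnotatedEntry(
            entry=entry, resolved_chrom=chrom, resolved_start=start,
            resolved_end=end, resolution="given_coords", load_order=k))
    return out


def group_entries_by_dataset(entries: Sequence[AnnotatedEntry]):
    """Package loose annotated entries as (Dataset, entries) pairs for the
    sweep-line builder, preserving each entry's load order."""
    from .ingest import Dataset

    by_ds: dict[str, list[AnnotatedEntry]] = {}
    order: dict[str, int] = {}
    for e in entries:
        by_ds.setdefault(e.dataset_id, []).append(e)
        order[e.dataset_id] = e.load_order
    out = []
    for ds_id in sorted(by_ds, key=lambda d: order[d]):
        ds = Dataset(dataset_id=ds_id,
                     data_type=by_ds[ds_id][0].data_type,
                     entries=[e.entry for e in by_ds[ds_id]],
                     load_order=order[ds_id])
        out.append((ds, by_ds[ds_id]))
    return out
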