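"""Regional-unit construction: worked examples, oracle equivalence,
invariants, key-based merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regionamalgam as ra
from regionamalgam.fixtures import (
    group_entries_by_dataset,
    oracle_regional_units,
    random_annotated_entries,
)
from regionamalgam.ingest import AnnotatedEntry, Dataset, DatasetEntry
from regionamalgam.merge import MergeError


def ann(ds, chrom, start, end, name=None, load_order=0, data_type="t",
        row=0, **passthrough):
    entry = DatasetEntry(dataset_id=ds, data_type=data_type,
                         entity_name=name, chrom=chrom, start=start, end=end,
                         passthrough={k: str(v) for k, v in passthrough.items()},
                         row_number=row)
    return AnnotatedEntry(entry=entry, resolved_chrom=chrom,
                          resolved_start=start, resolved_end=end,
                          resolution="given_coords", load_order=load_order)


def build(entries):
    return ra.build_regional_units(group_entries_by_dataset(entries))


class TestWorkedExamples:
    def test_single_entry_forms_singleton_unit(self):
        m = build([ann("ds1", "1", 100, 200, "A")])
        u = m.units[0]
        assert (u.start_flag, u.stop_flag) == (100, 200)
        assert u.subregions == []

    def test_chain_merge_envelope_and_widest_defining_entity(self):
        a = ann("ds1", "1", 100, 300, "A", load_order=0)
        b = ann("ds2", "1", 250, 400, "B", load_order=1)
        c = ann("ds2", "1", 500, 600, "C", load_order=1)
        m = build([a, b, c])
        assert len(m.units) == 2
        u1, u2 = m.units
        assert (u1.chrom, u1.start_flag, u1.stop_flag) == ("1", 100, 400)
        assert u1.defining_entry is a           # 201 bp >= 151 bp
        assert u1.origin_dataset == "ds1"
        assert u1.subregions == [b]
        assert (u2.start_flag, u2.stop_flag) == (500, 600)
        assert u2.defining_entry is c

    def test_equal_length_tie_broken_by_dataset_load_order(self):
        a = ann("ds1", "2", 10, 20, "A", load_order=0)
        b = ann("ds2", "2", 10, 20, "B", load_order=1)
        m = build([a, b])
        assert len(m.units) == 1
        assert m.units[0].defining_entry is a
        assert m.units[0].subregions == [b]

    def test_abutting_entries_do_not_merge(self):
        m = build([ann("ds1", "3", 100, 200, "A"),
                   ann("ds1", "3", 201, 300, "B", row=1)])
        assert len(m.units) == 2

    def test_one_shared_base_is_enough_to_merge(self):
        m = build([ann("ds1", "3", 100, 200, "A"),
                   ann("ds1", "3", 200, 300, "B", row=1)])
        assert len(m.units) == 1
        assert (m.units[0].start_flag, m.units[0].stop_flag) == (100, 300)

    def test_no_mapped_entries_raises_empty_vocabulary(self):
        ds = Dataset(dataset_id="d", data_type="t", entries=[])
        with pytest.raises(MergeError, match="empty vocabulary"):
            ra.build_regional_units([(ds, [])])


class TestOracleAndInvariants:
    def test_sweep_line_equals_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            entries = random_annotated_entries(rng)
            got = build(entries)
            expected = oracle_regional_units(entries)
            assert ra.maps_equal(got, expected)
            ra.validate_merged_map(got)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(0, 2),            # dataset index
                  st.integers(1, 300),          # start
                  st.integers(0, 60)),          # length - 1
        min_size=1, max_size=25))
    def test_any_interval_multiset_matches_oracle(self, raw):
        entries = [ann(f"ds{k + 1}", "1", s, s + l, f"E{i}",
                       load_order=k, row=i)
                   for i, (k, s, l) in enumerate(raw)]
        got = build(entries)
        assert ra.maps_equal(got, oracle_regional_units(entries))
        ra.validate_merged_map(got)

    def test_conservation_every_entry_lands_in_exactly_one_unit(self):
        rng = np.random.default_rng(5)
        entries = random_annotated_entries(rng, max_intervals=60)
        m = build(entries)
        assert m.n_entries == len(entries)
        seen = {id(e) for _, e in m.iter_entries()}
        assert len(seen) == len(entries)

    def test_union_of_unit_spans_equals_union_of_entry_spans(self):
        rng = np.random.default_rng(6)
        entries = random_annotated_entries(rng, max_intervals=40,
                                           coord_space=2000, max_len=100)
        m = build(entries)
        entry_bp = {(e.resolved_chrom, p) for e in entries
                    for p in range(e.resolved_start, e.resolved_end + 1)}
        unit_bp = {(u.chrom, p) for u in m.units
                   for p in range(u.start_flag, u.stop_flag + 1)}
        assert entry_bp == unit_bp

    def test_dataset_order_permutation_keeps_spans_and_membership(self):
        rng = np.random.default_rng(7)
        entries = random_annotated_entries(rng, max_intervals=50)
        m1 = build(entries)
        permuted = []
        for e in entries:
            flipped = ann(e.dataset_id, e.resolved_chrom, e.resolved_start,
                          e.resolved_end, e.entity_name,
                          load_order=2 - e.load_order,
                          row=e.entry.row_number)
            permuted.append(flipped)
        m2 = build(permuted)
        spans1 = [(u.chrom, u.start_flag, u.stop_flag, u.n_entries)
                  for u in m1.units]
        spans2 = [(u.chrom, u.start_flag, u.stop_flag, u.n_entries)
                  for u in m2.units]
        assert spans1 == spans2

    def test_rebuilding_from_a_maps_entries_is_idempotent(self):
        rng = np.random.default_rng(8)
        entries = random_annotated_entries(rng)
        m1 = build(entries)
        m2 = build([e for _, e in m1.iter_entries()])
        assert ra.maps_equal(m1, m2)


class TestOracleItself:
    def test_disjoint_singletons_stay_singletons(self):
        entries = [ann("ds1", "1", i * 100, i * 100 + 10, f"E{i}", row=i)
                   for i in range(1, 5)]
        m = oracle_regional_units(entries)
        assert len(m.units) == 4
        assert all(not u.subregions for u in m.units)

    def test_nested_chain_collapses_to_outermost(self):
        entries = [ann("ds1", "1", 100 + 10 * i, 600 - 10 * i, f"N{i}", row=i)
                   for i in range(5)]
        m = oracle_regional_units(entries)
        assert len(m.units) == 1
        u = m.units[0]
        assert (u.start_flag, u.stop_flag) == (100, 600)
        assert u.defining_entry.entity_name == "N0"


class TestKeyMerge:
    def make_ds(self, ds_id, keys, load_order, data_type="t"):
        entries = [DatasetEntry(dataset_id=ds_id, data_type=data_type,
                                entity_name=None, chrom="1",
                                start=10 * (i + 1), end=10 * (i + 1) + 5,
                                passthrough={"probe_set": k}, row_number=i)
                   for i, k in enumerate(keys)]
        return Dataset(dataset_id=ds_id, data_type=data_type, entries=entries,
                       load_order=load_order,
                       passthrough_columns=["probe_set"])

    def test_units_are_the_union_of_key_values(self):
        ds1 = self.make_ds("ds1", ["P1", "P2"], 0)
        ds2 = self.make_ds("ds2", ["p2", "P3"], 1)
        m = ra.merge_by_key([ds1, ds2], "probe_set")
        by_key = {u.key.upper(): u for u in m.units}
        assert set(by_key) == {"P1", "P2", "P3"}
        assert by_key["P2"].n_entries == 2           # case-insensitive join
        assert by_key["P2"].origin_dataset == "ds1"  # load-order tie-break
        assert by_key["P1"].n_entries == by_key["P3"].n_entries == 1

    def test_single_dataset_yields_one_unit_per_distinct_key(self):
        m = ra.merge_by_key([self.make_ds("ds1", ["A", "B", "C"], 0)],
                            "probe_set")
        assert len(m.units) == 3

    def test_empty_key_row_is_reported_malformed(self):
        ds = self.make_ds("ds1", ["A", ""], 0)
        m = ra.merge_by_key([ds], "probe_set")
        assert len(m.units) == 1
        assert m.unmapped.entries[0][2] == "malformed-key"

    def test_missing_key_column_names_the_dataset(self):
        ds = self.make_ds("ds2", ["A"], 0)
        with pytest.raises(MergeError, match="ds2"):
            ra.merge_by_key([ds], "nonexistent")

    def test_mixed_chromosome_unit_carries_no_coordinates(self):
        e1 = DatasetEntry(dataset_id="ds1", data_type="t", entity_name=None,
                          chrom="1", start=10, end=20,
                          passthrough={"k": "P"}, row_number=0)
        e2 = DatasetEntry(dataset_id="ds1", data_type="t", entity_name=None,
                          chrom="2", start=10, end=20,
                          passthrough={"k": "P"}, row_number=1)
        ds = Dataset(dataset_id="ds1", data_type="t", entries=[e1, e2],
                     load_order=0, passthrough_columns=["k"])
        m = ra.merge_by_key([ds], "k")
        assert m.units[0].chrom is None
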