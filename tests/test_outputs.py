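"""Txt/HTML/BED/FASTA writers, summaries and search."""

import pytest

import regionamalgam as ra
from regionamalgam.outputs import UrlTemplates

from test_merge import ann, build


@pytest.fixture
def three_entry_map():
    a = ann("ds1", "1", 100, 300, "A", load_order=0, data_type="expr", Value=1)
    b = ann("ds2", "1", 250, 400, "B", load_order=1, data_type="cnv")
    c = ann("ds2", "1", 500, 600, "C", load_order=1, data_type="cnv", row=1)
    m = build([a, b, c])
    m.provenance["datasets"] = [
        {"id": "ds1", "data_type": "expr", "passthrough": ["Value"]},
        {"id": "ds2", "data_type": "cnv", "passthrough": []},
    ]
    return m


def data_rows(path):
    lines = path.read_text().splitlines()
    body = [l for l in lines if not l.startswith("#")]
    header = body[0].split("\t")
    return header, [dict(zip(header, l.split("\t"))) for l in body[1:]]


class TestTxt:
    def test_rows_grouped_by_unit_with_shared_flags(self, three_entry_map,
                                                    tmp_path):
        p = ra.write_txt(three_entry_map, tmp_path / "m.txt", deterministic=True)
        header, rows = data_rows(p)
        assert header[:7] == ["Chrom", "StartFlag", "StopFlag", "Start",
                              "Stop", "EntityName", "DataType"]
        assert len(rows) == 3
        assert [r["StartFlag"] for r in rows] == ["100", "100", "500"]
        assert [r["StopFlag"] for r in rows] == ["400", "400", "600"]
        assert rows[0]["IsDefining"] == "1" and rows[1]["IsDefining"] == "0"

    def test_singleton_units_have_start_equal_startflag(self, tmp_path):
        m = build([ann("ds1", "1", 5, 9, "A"), ann("ds1", "2", 7, 11, "B", row=1)])
        _, rows = data_rows(ra.write_txt(m, tmp_path / "m.txt",
                                         deterministic=True))
        for r in rows:
            assert r["Start"] == r["StartFlag"] and r["Stop"] == r["StopFlag"]

    def test_missing_passthrough_cells_are_empty(self, three_entry_map,
                                                 tmp_path):
        _, rows = data_rows(ra.write_txt(three_entry_map, tmp_path / "m.txt",
                                         deterministic=True))
        assert rows[0]["Value"] == "1"      # ds1 carries Value
        assert rows[1]["Value"] == ""       # ds2 has no such column

    def test_deterministic_flag_gives_byte_identical_reruns(
            self, three_entry_map, tmp_path):
        p1 = ra.write_txt(three_entry_map, tmp_path / "a.txt", deterministic=True)
        p2 = ra.write_txt(three_entry_map, tmp_path / "b.txt", deterministic=True)
        assert p1.read_bytes() == p2.read_bytes()


class TestHtml:
    def test_unit_header_rows_and_entry_rows(self, three_entry_map, tmp_path):
        p = ra.write_html(three_entry_map, tmp_path / "m.html")
        text = p.read_text()
        assert text.count('class="unit"') == 2
        assert text.count("<tr") == 1 + 2 + 3  # header + units + entries

    def test_assigned_gene_cells_link_to_all_three_databases(self, tmp_path):
        e = ann("ds1", "13", 100, 500, "BRCA2")
        e.assigned_gene = "BRCA2"
        m = build([e])
        text = ra.write_html(m, tmp_path / "m.html").read_text()
        assert "term=BRCA2" in text
        assert "ensembl.org" in text and "genome.ucsc.edu" in text

    def test_gene_less_cells_carry_no_anchor(self, three_entry_map, tmp_path):
        text = ra.write_html(three_entry_map, tmp_path / "m.html").read_text()
        assert "<a href" not in text  # no entry has an assigned gene

    def test_templates_require_a_placeholder(self):
        with pytest.raises(ValueError, match="placeholder"):
            UrlTemplates(ncbi="https://example.org/static")


class TestBed:
    def test_unit_level_start_is_decremented_once(self, three_entry_map,
                                                  tmp_path):
        p, skipped = ra.export_bed(three_entry_map, tmp_path / "m.bed")
        lines = [l.split("\t") for l in p.read_text().splitlines()]
        assert skipped == 0
        assert lines[0][:3] == ["chr1", "99", "400"]
        assert lines[1][:3] == ["chr1", "499", "600"]

    def test_entry_level_emits_one_line_per_member(self, three_entry_map,
                                                   tmp_path):
        p, _ = ra.export_bed(three_entry_map, tmp_path / "m.bed",
                             level="entries")
        assert len(p.read_text().splitlines()) == 3

    def test_bed_conversion_round_trips_exactly(self, three_entry_map,
                                                tmp_path):
        p, _ = ra.export_bed(three_entry_map, tmp_path / "m.bed")
        for line, unit in zip(p.read_text().splitlines(),
                              three_entry_map.units):
            _, s0, e = line.split("\t")[:3]
            assert (int(s0) + 1, int(e)) == (unit.start_flag, unit.stop_flag)

    def test_coordinate_free_key_units_are_skipped_and_counted(self, tmp_path):
        from regionamalgam.ingest import Dataset, DatasetEntry
        entries = [DatasetEntry(dataset_id="d", data_type="t",
                                entity_name=None, chrom=c, start=1, end=5,
                                passthrough={"k": "P"}, row_number=i)
                   for i, c in enumerate(["1", "2"])]
        ds = Dataset(dataset_id="d", data_type="t", entries=entries,
                     load_order=0, passthrough_columns=["k"])
        m = ra.merge_by_key([ds], "k")
        _, skipped = ra.export_bed(m, tmp_path / "m.bed")
        assert skipped == 1


class TestSummary:
    def test_counts_and_coverage_per_chromosome(self, three_entry_map):
        s = ra.summarize(three_entry_map)
        row = s.table[s.table.chrom == "1"].iloc[0]
        assert row["units"] == 2
        assert row["ds1"] == 1 and row["ds2"] == 2
        assert row["covered_bp"] == (400 - 100 + 1) + (600 - 500 + 1)

    def test_totals_row_equals_column_sums(self, fixture_result):
        from conftest import run_pipeline
        merged, _ = run_pipeline(fixture_result)
        s = ra.summarize(merged)
        body = s.table[s.table.chrom != "TOTAL"]
        total = s.table[s.table.chrom == "TOTAL"].iloc[0]
        for col in s.table.columns[1:]:
            assert total[col] == body[col].sum()

    def test_unmapped_section_mirrors_report(self, fixture_result):
        from conftest import run_pipeline
        merged, _ = run_pipeline(fixture_result)
        s = ra.summarize(merged)
        assert s.unmapped_counts == merged.unmapped.counts()


class TestSearch:
    def test_search_by_entity_label(self, three_entry_map):
        hits = ra.search_units(three_entry_map, "b")
        assert len(hits) == 1 and hits[0].start_flag == 100

    def test_search_by_position_string(self, three_entry_map):
        hits = ra.search_units(three_entry_map, "1:100")
        assert len(hits) == 1

    def test_search_miss_is_empty(self, three_entry_map):
        assert ra.search_units(three_entry_map, "zzz") == []


class TestFasta:
    def write_reference(self, tmp_path):
        ref = tmp_path / "ref.fa"
        ref.write_text(">chr1\nACGTACGTAC\n>chr2\nTTTTGGGGCC\n")
        return ref

    def test_inclusive_substring_extraction(self, tmp_path):
        ref = self.write_reference(tmp_path)
        m = build([ann("ds1", "1", 2, 5, "U")])
        p, skipped = ra.extract_unit_fasta(m, ref, tmp_path / "u.fa")
        assert skipped == 0
        lines = p.read_text().splitlines()
        assert lines[0] == ">U::1:2-5"
        assert lines[1] == "CGTA"

    def test_units_on_absent_chromosomes_are_skipped(self, tmp_path):
        ref = self.write_reference(tmp_path)
        m = build([ann("ds1", "1", 2, 5, "U"), ann("ds1", "9", 1, 4, "V", row=1)])
        _, skipped = ra.extract_unit_fasta(m, ref, tmp_path / "u.fa")
        assert skipped == 1

    def test_gene_level_deduplicates_shared_assignments(self, tmp_path):
        ref = self.write_reference(tmp_path)
        a = ann("ds1", "1", 2, 5, "A")
        b = ann("ds2", "1", 3, 6, "B", load_order=1)
        for e in (a, b):
            e.assigned_gene = "GX"
            e.gene_span = ("1", 2, 6)
        m = build([a, b])
        p, _ = ra.extract_unit_fasta(m, ref, tmp_path / "g.fa", level="genes")
        text = p.read_text()
        assert text.count(">") == 1
        assert text.splitlines()[0] == ">GX::1:2-6"
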