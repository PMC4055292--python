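"""Shared fixtures: a tiny hand-written gene library and pipeline helpers."""

from __future__ import annotations

from pathlib import Path

import pytest

import regionamalgam as ra
from regionamalgam.fixtures import FixtureResult, FixtureSpec, generate_fixture

TINY_LIBRARY = """\
symbol	synonyms	chrom	start	end	strand	ncbi_id	ensembl_id
BRCA2	FANCD1|FAD	chr13	100	500	+	675	ENSG00000139618
G1		chr1	100	200	+	11	ENSG1
G2	S1	chr1	240	400	-	12	ENSG2
G3	S1	chr2	50	80	+	13	ENSG3
"""


@pytest.fixture
def tiny_library_path(tmp_path: Path) -> Path:
    p = tmp_path / "library.tsv"
    p.write_text(TINY_LIBRARY)
    return p


@pytest.fixture
def tiny_library(tiny_library_path) -> ra.GeneLibrary:
    return ra.load_gene_library(tiny_library_path)


@pytest.fixture(scope="session")
def fixture_result(tmp_path_factory) -> FixtureResult:
    """One shared synthetic study (seed 7) for the heavier tests."""
    d = tmp_path_factory.mktemp("fixture7")
    return generate_fixture(FixtureSpec(seed=7), d)


def run_pipeline(result: FixtureResult, policy=None, library=None):
    """Load -> annotate -> merge a generated fixture; returns (map, pairs)."""
    lib = library or ra.load_gene_library(result.library_path)
    pairs, unmapped = [], ra.UnmappedReport()
    for k, (path, ds_id, dtype) in enumerate(result.dataset_paths):
        ds = ra.load_dataset(path, None, ds_id, dtype, load_order=k)
        annotated, report = ra.annotate_dataset(ds, lib, policy)
        pairs.append((ds, annotated))
        unmapped.extend(report)
    provenance = {
        "assembly": "synthetic",
        "merge_mode": "coords",
        "datasets": [{"id": ds.dataset_id, "data_type": ds.data_type,
                      "passthrough": list(ds.passthrough_columns)}
                     for ds, _ in pairs],
    }
    merged = ra.build_regional_units(pairs, unmapped=unmapped,
                                     provenance=provenance)
    return merged, pairs
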