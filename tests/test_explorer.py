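"""Search engine: matching, ranking, filters, TSV export, snapshot loading."""

from __future__ import annotations

import csv

import pytest

from mdscout.errors import QueryError, SchemaError
from mdscout.explorer import SearchQuery, export_tsv, load_snapshot, search
from mdscout.records import DatasetRecord, FileRecord, IndexSnapshot, datasets_frame, files_frame


@pytest.fixture()
def small_index():
    datasets = [
        DatasetRecord(
            "zenodo", "Z1", doi="10.1/z1", title="Martini membrane simulations",
            description="coarse-grain lipid bilayer", publication_date="2022-01-01",
            n_files=2, total_size_bytes=100,
        ),
        DatasetRecord(
            "figshare", "F1", doi="10.1/f1", title="Atomistic protein dynamics",
            description="solvated lysozyme with a lipid probe", publication_date="2021-06-01",
            n_files=1, total_size_bytes=2000,
        ),
        DatasetRecord(
            "osf", "O1", doi="10.1/o1", title="Spectroscopy data",
            description="no simulations here", publication_date="2020-01-01",
            n_files=1, total_size_bytes=50,
        ),
    ]
    files = [
        FileRecord("zenodo", "Z1", "bilayer.gro", 60),
        FileRecord("zenodo", "Z1", "prod.mdp", 40),
        FileRecord("figshare", "F1", "traj.xtc", 2000),
        FileRecord("osf", "O1", "spectrum.dat", 50),
    ]
    return IndexSnapshot(
        datasets=datasets_frame(datasets), files=files_frame(files), harvest_date="2023-01-01"
    )


def test_single_keyword_hit(small_index):
    results = search(small_index, SearchQuery(keywords=["martini"]))
    assert len(results) == 1
    assert results[0].dataset_id == "Z1"
    assert results[0].score == 1
    assert "title" in results[0].matched_fields


def test_empty_query_matches_everything(small_index):
    results = search(small_index, SearchQuery())
    assert {r.dataset_id for r in results} == {"Z1", "F1", "O1"}


def test_multi_keyword_score_ranks_higher(small_index):
    results = search(small_index, SearchQuery(keywords=["lipid", "membrane"]))
    assert [r.dataset_id for r in results] == ["Z1", "F1"]
    assert results[0].score == 2 and results[1].score == 1


def test_filters_are_conjunctive_and_monotonic(small_index):
    base = search(small_index, SearchQuery())
    filtered = search(small_index, SearchQuery(extension="gro"))
    assert {r.dataset_id for r in filtered} == {"Z1"}
    assert len(filtered) <= len(base)
    engine = search(small_index, SearchQuery(engine="gromacs"))
    assert {r.dataset_id for r in engine} == {"Z1", "F1"}
    dated = search(small_index, SearchQuery(date_from="2021-01-01", date_to="2021-12-31"))
    assert {r.dataset_id for r in dated} == {"F1"}
    sized = search(small_index, SearchQuery(size_min_bytes=1000))
    assert {r.dataset_id for r in sized} == {"F1"}


def test_malformed_date_range_raises(small_index):
    with pytest.raises(QueryError):
        search(small_index, SearchQuery(date_from="01/02/2020"))


def test_export_tsv_row_count_and_sanitization(small_index, tmp_path):
    small_index.datasets.loc[
        small_index.datasets["dataset_id"] == "Z1", "description"
    ] = "has\ttab and\nnewline"
    results = search(small_index, SearchQuery())
    out = tmp_path / "hits.tsv"
    n_rows = export_tsv(results, out)
    assert n_rows == sum(len(r.file_rows) for r in results) == 4
    with open(out, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    assert len(rows) == 5  # header + 4 data rows
    widths = {len(r) for r in rows}
    assert widths == {len(rows[0])}
    urls = {r[3] for r in rows[1:]}
    assert any("zenodo.org" in u for u in urls)


def test_export_empty_results(tmp_path):
    out = tmp_path / "empty.tsv"
    assert export_tsv([], out) == 0
    assert out.read_text().strip()  # header only


def test_snapshot_roundtrip_and_schema_errors(small_index, tmp_path):
    small_index.save(tmp_path / "snap")
    loaded = load_snapshot(tmp_path / "snap")
    assert len(loaded.datasets) == 3
    assert loaded.harvest_date == "2023-01-01"

    broken = small_index.datasets.drop(columns=["dataset_id"])
    broken.to_parquet(tmp_path / "snap" / "datasets.parquet", index=False)
    with pytest.raises(SchemaError) as err:
        load_snapshot(tmp_path / "snap")
    assert "dataset_id" in str(err.value)


def test_load_external_snapshot_with_alias_columns(tmp_path):
    """Synthetic stand-in for an externally deposited snapshot: alias column
    names are renamed onto the package schema and aggregates recomputed."""
    import pandas as pd

    from mdscout.explorer import load_external_snapshot

    datasets = pd.DataFrame(
        {
            "dataset_origin": ["zenodo"],
            "dataset_id": ["777"],
            "doi": ["10.5072/777"],
            "title": ["external"],
            "description": [""],
            "date_creation": ["2022-02-02"],
        }
    )
    files = pd.DataFrame(
        {
            "dataset_origin": ["zenodo"] * 3,
            "dataset_id": ["777"] * 3,
            "file_name": ["a.gro", "archive.zip", "inner/b.mdp"],
            "file_size_in_bytes": [10, 100, 20],
            "from_zip_file": [False, False, True],
            "origin_zip_file": ["", "", "archive.zip"],
        }
    )
    datasets.to_parquet(tmp_path / "datasets.parquet", index=False)
    files.to_parquet(tmp_path / "files.parquet", index=False)
    snapshot = load_external_snapshot(tmp_path)
    row = snapshot.datasets.iloc[0]
    assert row["repository"] == "zenodo"
    assert row["n_files"] == 2
    assert row["n_zip_files"] == 1
    assert row["n_files_within_zip"] == 1
    assert row["total_size_bytes"] == 110
    assert set(snapshot.files["file_extension"]) == {"gro", "zip", "mdp"}
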