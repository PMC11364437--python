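"""Repository client behaviour against hand-built recorded fixtures."""

from __future__ import annotations

import pytest

from mdscout.errors import (
    ConfigurationError,
    ExtractionError,
    MissingDatasetError,
    UnsupportedPreviewError,
)
from mdscout.records import FileRecord
from mdscout.repo_clients import (
    SEARCH_PAGE_SIZE,
    CLIENTS,
    FileTypeEntry,
    Query,
    QueryConfig,
    ZENODO_PREVIEW_LIMIT,
    build_queries,
    fetch_dataset,
    fetch_file,
    normalize_date,
    parse_zip_preview,
    search_datasets,
)
from mdscout.transport import FixtureTransport, FixtureWriter


# -- query construction -----------------------------------------------------


def test_build_queries_expands_extensions_and_keywords():
    config = QueryConfig(
        file_types=[FileTypeEntry("mdp"), FileTypeEntry("log", keyword_required=True)],
        keywords=["gromacs", "namd"],
    )
    queries = build_queries(config)
    assert queries == [
        Query("mdp", "", False),
        Query("log", "gromacs", True),
        Query("log", "namd", True),
    ]


def test_build_queries_rejects_empty_extension_list():
    with pytest.raises(ConfigurationError):
        build_queries(QueryConfig(file_types=[], keywords=["gromacs"]))


def test_query_requires_keyword_when_flagged():
    with pytest.raises(ConfigurationError):
        Query("log", "", keyword_required=True)


# -- search pagination ------------------------------------------------------


def _write_zenodo_search(writer, query, pages, total):
    client = CLIENTS["zenodo"]
    for page_no, ids in enumerate(pages, start=1):
        payload = {"hits": {"hits": [{"id": i} for i in ids], "total": total}}
        writer.record("zenodo", "search", client.search_params(query, page_no), payload)


def test_search_traverses_all_pages_and_dedupes(tmp_path):
    query = Query("gro")
    ids_page1 = [f"d{i}" for i in range(SEARCH_PAGE_SIZE)]
    ids_page2 = ["d0", "x1", "x2"]  # d0 repeated across pages
    writer = FixtureWriter(tmp_path)
    _write_zenodo_search(writer, query, [ids_page1, ids_page2], total=SEARCH_PAGE_SIZE + 2)
    writer.flush()
    ids = search_datasets("zenodo", query, FixtureTransport(tmp_path))
    # brute-force union over the fixture pages
    expected = list(dict.fromkeys(ids_page1 + ids_page2))
    assert ids == expected
    assert len(ids) == SEARCH_PAGE_SIZE + 2


def test_search_zero_hits(tmp_path):
    query = Query("gro")
    writer = FixtureWriter(tmp_path)
    _write_zenodo_search(writer, query, [[]], total=0)
    writer.flush()
    assert search_datasets("zenodo", query, FixtureTransport(tmp_path)) == []


# -- dataset fetch ----------------------------------------------------------


def _zenodo_record(dataset_id, version, date, files):
    return {
        "id": dataset_id,
        "doi": f"10.5072/{dataset_id}",
        "version": version,
        "metadata": {
            "title": "t",
            "description": "d",
            "publication_date": date,
            "license": "cc-by-4.0",
        },
        "files": [{"key": n, "size": s, "links": {"self": f"fixture://files/{n}"}} for n, s in files],
    }


def test_fetch_dataset_lists_files(tmp_path):
    writer = FixtureWriter(tmp_path)
    payload = _zenodo_record("42", "v1", "2021-05-01", [("a.gro", 10), ("b.mdp", 20), ("c.zip", 30)])
    writer.record("zenodo", "record", CLIENTS["zenodo"].record_params("42"), payload)
    writer.flush()
    record = fetch_dataset("zenodo", "42", FixtureTransport(tmp_path))
    assert len(record.file_entries) == 3
    assert record.publication_date == "2021-05-01"


def test_fetch_dataset_keeps_latest_version(tmp_path):
    writer = FixtureWriter(tmp_path)
    old = _zenodo_record("42", "v1", "2020-01-01", [("a.gro", 10)])
    new = _zenodo_record("42", "v2", "2022-01-01", [("a.gro", 10), ("b.gro", 11)])
    writer.record("zenodo", "record", CLIENTS["zenodo"].record_params("42"), {"versions": [new, old]})
    writer.flush()
    record = fetch_dataset("zenodo", "42", FixtureTransport(tmp_path))
    assert record.version_tag == "v2"
    assert len(record.file_entries) == 2


def test_fetch_dataset_unknown_id(tmp_path):
    writer = FixtureWriter(tmp_path)
    writer.flush()
    with pytest.raises(MissingDatasetError):
        fetch_dataset("zenodo", "nope", FixtureTransport(tmp_path))


# -- zip previews -----------------------------------------------------------


def _zenodo_preview(members):
    rows = "".join(f"<tr><td>{n}</td><td>{s}</td></tr>" for n, s in members)
    return f"<html><table class='preview-table'><tr><th>N</th><th>S</th></tr>{rows}</table></html>"


def test_zenodo_preview_entries_and_sizes():
    members = [("a/topol.top", 123), ("b.gro", 456)]
    preview = parse_zip_preview(_zenodo_preview(members), "zenodo")
    assert preview.entries == members
    assert not preview.truncated
    # preview fidelity: sizes survive parsing exactly
    assert sum(s for _, s in preview.entries) == 579


def test_zenodo_preview_truncates_at_limit():
    members = [(f"f{i}.dat", i) for i in range(ZENODO_PREVIEW_LIMIT)]
    preview = parse_zip_preview(_zenodo_preview(members), "zenodo")
    assert preview.truncated
    assert len(preview.entries) == ZENODO_PREVIEW_LIMIT


def test_figshare_preview_dialect():
    html = (
        "<ul class='file-list'>"
        "<li><span class='filename'>x.mdp</span><span class='file-size'>17</span></li>"
        "</ul>"
    )
    preview = parse_zip_preview(html, "figshare")
    assert preview.entries == [("x.mdp", 17)]


def test_empty_preview_table():
    assert parse_zip_preview("<html><table class='preview-table'></table></html>", "zenodo").entries == []


def test_osf_has_no_preview():
    with pytest.raises(UnsupportedPreviewError):
        parse_zip_preview("<html></html>", "osf")


# -- selective download -----------------------------------------------------


def test_fetch_file_caches_plain_files(tmp_path):
    writer = FixtureWriter(tmp_path / "fx")
    url = writer.add_file("zenodo/42/run.mdp", b"dt = 0.002\n")
    writer.flush()
    transport = FixtureTransport(tmp_path / "fx")
    entry = FileRecord("zenodo", "42", "run.mdp", 11, download_url=url)
    cache = tmp_path / "cache"
    path = fetch_file(entry, cache, transport)
    assert path.read_bytes() == b"dt = 0.002\n"

    class NoNetwork:
        def get_bytes(self, url):  # pragma: no cover - must not be called
            raise AssertionError("cache miss on second fetch")

    assert fetch_file(entry, cache, NoNetwork()) == path


def test_fetch_file_extracts_single_zip_member(tmp_path):
    import io, zipfile

    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        zf.writestr("a/topol.top", "[ system ]\n")
        zf.writestr("b.gro", "x")
    writer = FixtureWriter(tmp_path / "fx")
    url = writer.add_file("zenodo/42/data.zip", buf.getvalue())
    writer.flush()
    transport = FixtureTransport(tmp_path / "fx")
    member = FileRecord(
        "zenodo", "42", "a/topol.top", 11, from_zip=True, origin_zip="data.zip", download_url=url
    )
    path = fetch_file(member, tmp_path / "cache", transport)
    assert path.read_text() == "[ system ]\n"

    missing = FileRecord(
        "zenodo", "42", "nope.gro", 1, from_zip=True, origin_zip="data.zip", download_url=url
    )
    with pytest.raises(ExtractionError):
        fetch_file(missing, tmp_path / "cache", transport)


# -- date normalization -----------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("2021-05-01", "2021-05-01"),
        ("2021-05-01T10:00:00Z", "2021-05-01"),
        ("19/11/2014", "2014-11-19"),
    ],
)
def test_normalize_date(raw, expected):
    assert normalize_date(raw) == expected
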