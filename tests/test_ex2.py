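"""Explore/expand/clean/merge semantics."""

from __future__ import annotations

import pandas as pd

from mdscout import ex2
from mdscout.records import DatasetRecord, FileRecord, IndexSnapshot, datasets_frame, files_frame
from mdscout.repo_clients import CLIENTS, Query
from mdscout.transport import FixtureTransport, FixtureWriter


def _search_fixture(writer, repo, query, ids):
    client = CLIENTS[repo]
    if repo == "zenodo":
        payload = {"hits": {"hits": [{"id": i} for i in ids], "total": len(ids)}}
    elif repo == "figshare":
        payload = [{"id": i} for i in ids]
    else:
        payload = {"data": [{"id": i} for i in ids], "links": {"next": None}}
    writer.record(repo, "search", client.search_params(query, 1), payload)


def test_explore_unions_hits_across_queries(tmp_path):
    writer = FixtureWriter(tmp_path)
    q1, q2 = Query("gro"), Query("mdp")
    _search_fixture(writer, "zenodo", q1, ["A", "B"])
    _search_fixture(writer, "zenodo", q2, ["B", "C"])
    writer.flush()
    found = ex2.explore(["zenodo"], [q1, q2], FixtureTransport(tmp_path))
    assert found == {("zenodo", "A"), ("zenodo", "B"), ("zenodo", "C")}


def test_explore_no_hits(tmp_path):
    writer = FixtureWriter(tmp_path)
    _search_fixture(writer, "zenodo", Query("gro"), [])
    writer.flush()
    assert ex2.explore(["zenodo"], [Query("gro")], FixtureTransport(tmp_path)) == set()


def test_explore_tags_ids_by_repository(tmp_path):
    writer = FixtureWriter(tmp_path)
    for repo in ("zenodo", "figshare", "osf"):
        _search_fixture(writer, repo, Query("gro"), ["same-id"])
    writer.flush()
    found = ex2.explore(["zenodo", "figshare", "osf"], [Query("gro")], FixtureTransport(tmp_path))
    assert len(found) == 3  # no cross-repository merging


def _zip_dataset_fixture(tmp_path):
    """One zenodo dataset: run.mdp + traj.zip containing a.gro and b.log."""
    import io, zipfile

    writer = FixtureWriter(tmp_path)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        zf.writestr("a.gro", "g")
        zf.writestr("b.log", "l")
    zip_url = writer.add_file("zenodo/D1/traj.zip", buf.getvalue())
    mdp_url = writer.add_file("zenodo/D1/run.mdp", b"dt=0.002\n")
    payload = {
        "id": "D1",
        "doi": "10.5072/D1",
        "version": "v1",
        "metadata": {"title": "t", "description": "", "publication_date": "2021-01-01", "license": ""},
        "files": [
            {"key": "run.mdp", "size": 9, "links": {"self": mdp_url}},
            {"key": "traj.zip", "size": len(buf.getvalue()), "links": {"self": zip_url}},
        ],
    }
    writer.record("zenodo", "record", CLIENTS["zenodo"].record_params("D1"), payload)
    preview = (
        "<html><table class='preview-table'>"
        "<tr><td>a.gro</td><td>1</td></tr><tr><td>b.log</td><td>1</td></tr>"
        "</table></html>"
    )
    writer.record("zenodo", "preview", CLIENTS["zenodo"].preview_params("D1", "traj.zip"), preview, kind="html")
    writer.flush()
    return FixtureTransport(tmp_path)


def test_expand_catalogues_plain_and_zip_members(tmp_path):
    transport = _zip_dataset_fixture(tmp_path)
    snapshot = ex2.expand({("zenodo", "D1")}, transport, harvest_date="2023-01-01")
    ds = snapshot.datasets.iloc[0]
    assert ds["n_files"] == 2
    assert ds["n_zip_files"] == 1
    assert ds["n_files_within_zip"] == 2
    members = snapshot.files[snapshot.files["from_zip"]]
    assert sorted(members["file_name"]) == ["a.gro", "b.log"]
    assert set(members["origin_zip"]) == {"traj.zip"}


def test_expand_skips_failing_dataset(tmp_path):
    transport = _zip_dataset_fixture(tmp_path)
    snapshot = ex2.expand({("zenodo", "D1"), ("zenodo", "GONE")}, transport, harvest_date="2023-01-01")
    assert list(snapshot.datasets["dataset_id"]) == ["D1"]


def _index(datasets, files, date="2023-01-01"):
    return IndexSnapshot(
        datasets=datasets_frame(datasets), files=files_frame(files), harvest_date=date
    )


def _ds(repo, did, **kw):
    defaults = dict(doi="", title="", description="", publication_date="2021-01-01")
    defaults.update(kw)
    return DatasetRecord(repository=repo, dataset_id=did, **defaults)


def test_clean_removes_dataset_with_only_irrelevant_zip_content():
    index = _index(
        [_ds("zenodo", "A"), _ds("zenodo", "B")],
        [
            FileRecord("zenodo", "A", "doc.zip", 10),
            FileRecord("zenodo", "A", "x.docx", 5, from_zip=True, origin_zip="doc.zip"),
            FileRecord("zenodo", "A", "y.png", 5, from_zip=True, origin_zip="doc.zip"),
            FileRecord("zenodo", "B", "one.gro", 5),
            *[FileRecord("zenodo", "B", f"junk{i}.txt", 1) for i in range(50)],
        ],
    )
    cleaned = ex2.clean(index, {"gro", "mdp", "xtc"})
    assert list(cleaned.datasets["dataset_id"]) == ["B"]
    # the retained dataset keeps every file, related or not
    assert len(cleaned.files) == 51


def test_clean_empty_index_and_idempotence():
    empty = _index([], [])
    assert ex2.clean(empty, {"gro"}).datasets.empty

    index = _index(
        [_ds("zenodo", "B")],
        [FileRecord("zenodo", "B", "one.gro", 5)],
    )
    once = ex2.clean(index, {"gro"})
    twice = ex2.clean(once, {"gro"})
    pd.testing.assert_frame_equal(once.datasets, twice.datasets)
    pd.testing.assert_frame_equal(once.files, twice.files)


def test_clean_never_adds_datasets(harvested):
    snapshot, _, _ = harvested
    recleaned = ex2.clean(snapshot, {"gro", "mdp", "xtc", "log", "top", "itp"})
    assert len(recleaned.datasets) <= len(snapshot.datasets)


def test_merge_disjoint_and_superseding():
    a = _index([_ds("zenodo", "A")], [FileRecord("zenodo", "A", "a.gro", 1)], date="2023-01-01")
    b = _index(
        [_ds("figshare", "B")], [FileRecord("figshare", "B", "b.gro", 1)], date="2023-02-01"
    )
    merged = ex2.merge_snapshots(a, b)
    assert len(merged.datasets) == 2
    assert merged.harvest_date == "2023-02-01"

    a2 = _index(
        [_ds("zenodo", "A", title="new")],
        [FileRecord("zenodo", "A", "a.gro", 1), FileRecord("zenodo", "A", "extra.mdp", 1)],
        date="2023-03-01",
    )
    merged2 = ex2.merge_snapshots(a, a2)
    assert merged2.datasets.iloc[0]["title"] == "new"
    assert len(merged2.files) == 2  # older file rows replaced atomically


def test_merge_self_is_identity():
    a = _index([_ds("zenodo", "A")], [FileRecord("zenodo", "A", "a.gro", 1)])
    merged = ex2.merge_snapshots(a, a)
    pd.testing.assert_frame_equal(merged.datasets, a.datasets)
    pd.testing.assert_frame_equal(merged.files, a.files)


def test_aggregate_conservation(harvested):
    """Per repository, dataset n_files totals equal the plain file rows."""
    snapshot, _, _ = harvested
    plain = snapshot.files[~snapshot.files["from_zip"]]
    for repo, sub in snapshot.datasets.groupby("repository"):
        assert sub["n_files"].sum() == len(plain[plain["repository"] == repo])


def test_replay_determinism(corpus, tmp_path):
    """Two harvests over the same fixture transport are byte-identical."""
    from mdscout.repo_clients import QueryConfig
    from mdscout.workflows import run_harvest

    root, _ = corpus
    snapshots = []
    for run in range(2):
        t = FixtureTransport(root)
        snap = run_harvest(["zenodo", "figshare", "osf"], QueryConfig.default(), t, harvest_date="2023-03-01")
        out = tmp_path / f"run{run}"
        snap.to_tsv(out)
        snapshots.append((out / "datasets.tsv").read_bytes() + (out / "files.tsv").read_bytes())
    assert snapshots[0] == snapshots[1]
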