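"""Search engine over an index snapshot.

Case-insensitive substring matching of keywords against dataset titles,
descriptions and file names, with conjunctive repository/engine/extension/
date/size filters; results rank by number of distinct keywords matched,
then newest publication date, then dataset id. Deliberately auditable:
no stemming, no fuzzy matching, no learned relevance.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import QueryError, SchemaError
from .inference import assign_engine
from .records import DATASET_COLUMNS, FILE_COLUMNS, IndexSnapshot

_WS = re.compile(r"[\t\r\n]+")

#: Columns of the exported TSV, one row per matching file.
EXPORT_COLUMNS = [
    "repository",
    "dataset_id",
    "doi",
    "dataset_url",
    "title",
    "publication_date",
    "file_name",
    "file_extension",
    "size_bytes",
    "from_zip",
    "origin_zip",
]

_DATASET_URL = {
    "zenodo": "https://zenodo.org/record/{id}",
    "figshare": "https://figshare.com/articles/dataset/{id}",
    "osf": "https://osf.io/{id}/",
}


def dataset_url(repository: str, dataset_id: str) -> str:
    template = _DATASET_URL.get(repository, "{id}")
    return template.format(id=dataset_id)


def _parse_date(text: str, what: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(text)
    except ValueError as exc:
        raise QueryError(f"malformed {what} date {text!r} (expect YYYY-MM-DD)") from exc


@dataclass
class SearchQuery:
    """Empty query (no keywords, no filters) matches every dataset."""

    keywords: list[str] = field(default_factory=list)
    repository: str | None = None
    engine: str | None = None
    extension: str | None = None
    date_from: str | None = None
    date_to: str | None = None
    size_min_bytes: int | None = None
    size_max_bytes: int | None = None
    include_zip_content: bool = True


@dataclass
class SearchResult:
    repository: str
    dataset_id: str
    score: int
    matched_fields: list[str]
    dataset_row: pd.Series
    file_rows: pd.DataFrame


def search(index: IndexSnapshot, query: SearchQuery) -> list[SearchResult]:
    """Ranked dataset hits with their matching file rows."""
    if query.date_from:
        date_from = _parse_date(query.date_from, "start")
    if query.date_to:
        date_to = _parse_date(query.date_to, "end")

    keywords = [k.lower() for k in query.keywords if k.strip()]
    results: list[SearchResult] = []
    for _, ds in index.datasets.iterrows():
        if query.repository and ds["repository"] != query.repository:
            continue
        if query.date_from or query.date_to:
            if not ds["publication_date"]:
                continue
            pub = _parse_date(str(ds["publication_date"]), "publication")
            if query.date_from and pub < date_from:
                continue
            if query.date_to and pub > date_to:
                continue

        files = index.files[
            (index.files["repository"] == ds["repository"])
            & (index.files["dataset_id"] == ds["dataset_id"])
        ]
        if not query.include_zip_content:
            files = files[~files["from_zip"]]
        if query.extension:
            files = files[files["file_extension"] == query.extension.lower().lstrip(".")]
        if query.engine:
            files = files[[assign_engine(e) == query.engine for e in files["file_extension"]]]
        if (query.extension or query.engine) and files.empty:
            continue
        if query.size_min_bytes is not None and int(ds["total_size_bytes"]) < query.size_min_bytes:
            continue
        if query.size_max_bytes is not None and int(ds["total_size_bytes"]) > query.size_max_bytes:
            continue

        title = str(ds["title"]).lower()
        description = str(ds["description"]).lower()
        names = [str(n).lower() for n in files["file_name"]]
        score = 0
        matched: list[str] = []
        for kw in keywords:
            fields_hit = []
            if kw in title:
                fields_hit.append("title")
            if kw in description:
                fields_hit.append("description")
            if any(kw in n for n in names):
                fields_hit.append("file_name")
            if fields_hit:
                score += 1
                matched.extend(f for f in fields_hit if f not in matched)
        if keywords and score == 0:
            continue
        results.append(
            SearchResult(
                repository=ds["repository"],
                dataset_id=ds["dataset_id"],
                score=score,
                matched_fields=matched,
                dataset_row=ds,
                file_rows=files,
            )
        )
    results.sort(key=lambda r: (-r.score, _sort_date(r.dataset_row["publication_date"]), r.dataset_id))
    return results


def _sort_date(value: str) -> str:
    # descending date: invert by using the complementary string
    text = str(value) if value else "0000-00-00"
    return "".join(chr(0x10FFFF - ord(c)) for c in text)


def _sanitize(value: object) -> str:
    return _WS.sub(" ", str(value))


def export_tsv(results: list[SearchResult], target: str | Path) -> int:
    """Write one row per matching file; returns the number of data rows.

    Embedded tabs/newlines in text fields are replaced by spaces so the
    column count survives any description.
    """
    target = Path(target)
    rows = []
    for result in results:
        ds = result.dataset_row
        for _, f in result.file_rows.iterrows():
            rows.append(
                {
                    "repository": ds["repository"],
                    "dataset_id": ds["dataset_id"],
                    "doi": _sanitize(ds["doi"]),
                    "dataset_url": dataset_url(ds["repository"], str(ds["dataset_id"])),
                    "title": _sanitize(ds["title"]),
                    "publication_date": ds["publication_date"],
                    "file_name": _sanitize(f["file_name"]),
                    "file_extension": f["file_extension"],
                    "size_bytes": int(f["size_bytes"]),
                    "from_zip": bool(f["from_zip"]),
                    "origin_zip": _sanitize(f["origin_zip"]),
                }
            )
    frame = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    frame.to_csv(target, sep="\t", index=False, encoding="utf-8")
    return len(rows)


def load_snapshot(path: str | Path) -> IndexSnapshot:
    """Load the two Parquet tables, validating the schema.

    Unknown extra columns are preserved; missing required columns raise a
    :class:`SchemaError` naming them.
    """
    path = Path(path)
    datasets = pd.read_parquet(path / "datasets.parquet")
    files = pd.read_parquet(path / "files.parquet")
    missing_d = [c for c in DATASET_COLUMNS if c not in datasets.columns]
    missing_f = [c for c in FILE_COLUMNS if c not in files.columns]
    if missing_d:
        raise SchemaError(missing_d, table="datasets")
    if missing_f:
        raise SchemaError(missing_f, table="files")
    date_file = path / "harvest_date.txt"
    harvest_date = date_file.read_text().strip() if date_file.exists() else ""
    return IndexSnapshot(datasets=datasets, files=files, harvest_date=harvest_date)


#: Column aliases seen in externally deposited snapshot tables.
EXTERNAL_ALIASES = {
    "dataset_origin": "repository",
    "origin": "repository",
    "date_creation": "publication_date",
    "date_created": "publication_date",
    "file_number": "n_files",
    "zip_file_number": "n_zip_files",
    "total_size_in_bytes": "total_size_bytes",
    "file_size_in_bytes": "size_bytes",
    "file_size": "size_bytes",
    "file_type": "file_extension",
    "from_zip_file": "from_zip",
    "in_zip_file": "from_zip",
    "origin_zip_file": "origin_zip",
    "file_url": "download_url",
}


def load_external_snapshot(path: str | Path) -> IndexSnapshot:
    """Load deposited snapshot tables whose columns use alias names.

    Renames known aliases onto this package's schema, fills schema columns
    the external tables lack, and recomputes per-dataset aggregates from
    the file rows so downstream analytics see a consistent snapshot.
    """
    path = Path(path)
    datasets = pd.read_parquet(path / "datasets.parquet").rename(columns=EXTERNAL_ALIASES)
    files = pd.read_parquet(path / "files.parquet").rename(columns=EXTERNAL_ALIASES)
    for frame, required, defaults in (
        (datasets, ("repository", "dataset_id"), {"doi": "", "title": "", "description": "",
                                                  "publication_date": "", "version_tag": "", "license": ""}),
        (files, ("repository", "dataset_id", "file_name"), {"size_bytes": 0, "from_zip": False,
                                                            "origin_zip": "", "download_url": ""}),
    ):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(missing, table="external snapshot")
        for col, default in defaults.items():
            if col not in frame.columns:
                frame[col] = default
    if "file_extension" not in files.columns:
        from .records import extension_of

        files["file_extension"] = [extension_of(n) for n in files["file_name"]]
    files["from_zip"] = files["from_zip"].astype(bool)

    # recompute aggregates from the file rows
    plain = files[~files["from_zip"]]
    members = files[files["from_zip"]]
    keys = ["repository", "dataset_id"]
    agg = plain.groupby(keys).agg(
        n_files=("file_name", "size"), total_size_bytes=("size_bytes", "sum")
    )
    agg["n_zip_files"] = plain[plain["file_extension"] == "zip"].groupby(keys)["file_name"].size()
    agg["n_files_within_zip"] = members.groupby(keys)["file_name"].size()
    agg = agg.fillna(0).astype(int).reset_index()
    for col in ("n_files", "total_size_bytes", "n_zip_files", "n_files_within_zip"):
        if col in datasets.columns:
            datasets = datasets.drop(columns=[col])
    datasets = datasets.merge(agg, on=keys, how="left")
    for col in ("n_files", "total_size_bytes", "n_zip_files", "n_files_within_zip"):
        datasets[col] = datasets[col].fillna(0).astype(int)
    from .records import DATASET_COLUMNS, FILE_COLUMNS

    return IndexSnapshot(
        datasets=datasets[[c for c in DATASET_COLUMNS] + [c for c in datasets.columns if c not in DATASET_COLUMNS]],
        files=files[[c for c in FILE_COLUMNS] + [c for c in files.columns if c not in FILE_COLUMNS]],
        harvest_date="",
    )
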