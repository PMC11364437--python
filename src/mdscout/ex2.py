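"""The Explore-and-Expand (Ex²) indexing strategy.

Explore: typed (extension, keyword) queries locate candidate datasets.
Expand: every file in a candidate dataset is catalogued — including members
of zip archives, read from the repository's HTML preview — on the working
assumption that files deposited together belong to one research project.
Clean: datasets whose catalogued content never touches the curated MD file
type list are discarded as false positives (a hazard of archive-based
discovery).
"""

from __future__ import annotations

import datetime
import logging

import pandas as pd

from .errors import HarvestError, MdscoutError, MergeError, UnsupportedPreviewError
from .records import (
    ARCHIVE_EXTENSIONS,
    DatasetRecord,
    FileRecord,
    IndexSnapshot,
    datasets_frame,
    extension_of,
    files_frame,
)
from .repo_clients import (
    CLIENTS,
    REPOSITORIES,
    Query,
    RawDatasetRecord,
    fetch_dataset,
    parse_zip_preview,
    search_datasets,
)
from .transport import Transport

log = logging.getLogger(__name__)


def explore(
    repos: list[str], queries: list[Query], transport: Transport
) -> set[tuple[str, str]]:
    """Union of all (repository, dataset_id) hits over repositories × queries.

    Harvest errors on one (repo, query) pair abort with a partial-result
    report attached; dataset ids are never merged across repositories.
    """
    found: set[tuple[str, str]] = set()
    for repo in repos:
        if repo not in REPOSITORIES:
            raise HarvestError(repo, "unknown repository")
        for query in queries:
            try:
                ids = search_datasets(repo, query, transport)
            except MdscoutError as exc:
                raise HarvestError(repo, f"{query}: {exc}; partial result: {len(found)} datasets") from exc
            found.update((repo, i) for i in ids)
    return found


def _dataset_rows(record: RawDatasetRecord, transport: Transport) -> list[FileRecord]:
    """Plain FileRecords plus previewed zip-member records for one dataset."""
    rows: list[FileRecord] = []
    for entry in record.file_entries:
        rows.append(
            FileRecord(
                repository=record.repository,
                dataset_id=record.dataset_id,
                file_name=entry.name,
                size_bytes=entry.size_bytes,
                download_url=entry.download_url,
            )
        )
        if extension_of(entry.name) in ARCHIVE_EXTENSIONS:
            if record.repository == "osf":
                continue  # OSF provides no zip preview; archives stay opaque
            client = CLIENTS[record.repository]
            try:
                markup = transport.get_text(
                    record.repository, "preview", client.preview_params(record.dataset_id, entry.name)
                )
                preview = parse_zip_preview(markup, record.repository)
            except UnsupportedPreviewError:
                continue  # OSF: archives stay opaque
            except MdscoutError as exc:
                log.warning(
                    "zip preview failed for %s/%s %s: %s — indexing archive without content",
                    record.repository, record.dataset_id, entry.name, exc,
                )
                continue
            if preview.truncated:
                log.warning(
                    "zip preview truncated for %s/%s %s (%d members listed)",
                    record.repository, record.dataset_id, entry.name, len(preview.entries),
                )
            for member, size in preview.entries:
                rows.append(
                    FileRecord(
                        repository=record.repository,
                        dataset_id=record.dataset_id,
                        file_name=member,
                        size_bytes=size,
                        from_zip=True,
                        origin_zip=entry.name,
                        download_url=entry.download_url,
                    )
                )
    return rows


def _aggregate(record: RawDatasetRecord, rows: list[FileRecord]) -> DatasetRecord:
    plain = [r for r in rows if not r.from_zip]
    members = [r for r in rows if r.from_zip]
    return DatasetRecord(
        repository=record.repository,
        dataset_id=record.dataset_id,
        doi=record.doi,
        title=record.title,
        description=record.description,
        publication_date=record.publication_date,
        version_tag=record.version_tag,
        license=record.license,
        n_files=len(plain),
        # plain files only: previewed members live inside archives already counted
        total_size_bytes=sum(r.size_bytes for r in plain),
        n_zip_files=sum(1 for r in plain if r.file_extension in ARCHIVE_EXTENSIONS),
        n_files_within_zip=len(members),
    )


def expand(
    candidates: set[tuple[str, str]], transport: Transport, harvest_date: str | None = None
) -> IndexSnapshot:
    """Catalogue the full content of every candidate dataset.

    A dataset whose fetch fails is skipped and logged; the harvest continues.
    """
    dataset_records: list[DatasetRecord] = []
    file_records: list[FileRecord] = []
    for repo, dataset_id in sorted(candidates):
        try:
            raw = fetch_dataset(repo, dataset_id, transport)
        except MdscoutError as exc:
            log.warning("skipping %s/%s: %s", repo, dataset_id, exc)
            continue
        rows = _dataset_rows(raw, transport)
        file_records.extend(rows)
        dataset_records.append(_aggregate(raw, rows))
    if harvest_date is None:
        harvest_date = datetime.date.today().isoformat()
    return IndexSnapshot(
        datasets=datasets_frame(dataset_records),
        files=files_frame(file_records),
        harvest_date=harvest_date,
    )


def clean(index: IndexSnapshot, target_extensions: set[str]) -> IndexSnapshot:
    """Drop datasets sharing no file type with the curated list.

    Inclusion is decided per dataset, never per file: one matching file
    (plain or inside a zip) keeps the whole dataset.
    """
    targets = {e.lower().lstrip(".") for e in target_extensions}
    if index.datasets.empty:
        return IndexSnapshot(
            datasets=index.datasets.copy(), files=index.files.copy(), harvest_date=index.harvest_date
        )
    hits = index.files[index.files["file_extension"].isin(targets)]
    keep = set(map(tuple, hits[["repository", "dataset_id"]].itertuples(index=False, name=None)))

    def _kept(frame: pd.DataFrame) -> pd.DataFrame:
        mask = [
            (repo, did) in keep
            for repo, did in frame[["repository", "dataset_id"]].itertuples(index=False, name=None)
        ]
        return frame[mask].reset_index(drop=True)

    return IndexSnapshot(
        datasets=_kept(index.datasets), files=_kept(index.files), harvest_date=index.harvest_date
    )


def merge_snapshots(a: IndexSnapshot, b: IndexSnapshot) -> IndexSnapshot:
    """Combine two harvests; for shared datasets the newer harvest wins.

    File rows are replaced atomically with their dataset row.
    """
    for frame in (a.datasets, b.datasets):
        bad = set(frame["repository"]) - set(REPOSITORIES)
        if bad:
            raise MergeError(f"unknown repository value(s): {sorted(bad)}")
    newer, older = (a, b) if a.harvest_date >= b.harvest_date else (b, a)
    newer_keys = set(
        map(tuple, newer.datasets[["repository", "dataset_id"]].itertuples(index=False, name=None))
    )

    def _not_superseded(frame: pd.DataFrame) -> pd.DataFrame:
        mask = [
            (repo, did) not in newer_keys
            for repo, did in frame[["repository", "dataset_id"]].itertuples(index=False, name=None)
        ]
        return frame[mask]

    datasets = pd.concat([newer.datasets, _not_superseded(older.datasets)], ignore_index=True)
    files = pd.concat([newer.files, _not_superseded(older.files)], ignore_index=True)
    return IndexSnapshot(datasets=datasets, files=files, harvest_date=newer.harvest_date)
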