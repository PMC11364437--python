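"""Uniform access to the Zenodo / Figshare / OSF repository APIs.

The three repositories answer with different response dialects (Zenodo's
``hits.hits`` envelope, Figshare's bare JSON lists, OSF's JSON:API
``data``/``links.next`` pages) and two of them expose an HTML preview of
zip-archive contents. One client class per repository hides the dialect;
everything flows through the swappable :class:`~mdscout.transport.Transport`
so harvests replay offline from recorded fixtures.
"""

from __future__ import annotations

import hashlib
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import lxml.html
import yaml

from .errors import (
    AccessError,
    ConfigurationError,
    ExtractionError,
    HarvestError,
    IntegrityError,
    MdscoutError,
    ParseError,
    UnsupportedPreviewError,
)
from .records import FileRecord, extension_of
from .transport import Transport

log = logging.getLogger(__name__)

REPOSITORIES = ("zenodo", "figshare", "osf")

#: Zenodo's zip preview lists at most this many members.
ZENODO_PREVIEW_LIMIT = 1000

SEARCH_PAGE_SIZE = 25


# -- queries ----------------------------------------------------------------


@dataclass(frozen=True)
class Query:
    """One (file type, optional keyword) search unit."""

    file_type: str
    keyword: str = ""
    keyword_required: bool = False

    def __post_init__(self) -> None:
        if not self.file_type:
            raise ConfigurationError("query file_type must be non-empty")
        if self.keyword_required and not self.keyword:
            raise ConfigurationError(f"file type {self.file_type!r} requires a keyword")


@dataclass
class FileTypeEntry:
    ext: str
    keyword_required: bool = False
    archive: bool = False


@dataclass
class QueryConfig:
    """Curated list of file types and keywords driving the explore phase."""

    file_types: list[FileTypeEntry] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QueryConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        file_types = [
            FileTypeEntry(
                ext=str(e["ext"]).lower().lstrip("."),
                keyword_required=bool(e.get("keyword_required", False)),
                archive=bool(e.get("archive", False)),
            )
            for e in raw.get("file_types", [])
        ]
        return cls(file_types=file_types, keywords=[str(k) for k in raw.get("keywords", [])])

    @classmethod
    def default(cls) -> "QueryConfig":
        from importlib.resources import files

        return cls.from_yaml(files("mdscout.data") / "query.yml")  # type: ignore[arg-type]

    def target_extensions(self) -> set[str]:
        """Extensions that mark a dataset as MD-relevant during cleaning.

        Archive types (zip) are discovery vehicles, not MD file types, and
        are excluded — otherwise no archive-borne false positive could ever
        be removed.
        """
        return {ft.ext for ft in self.file_types if not ft.archive}


def build_queries(config: QueryConfig) -> list[Query]:
    """Expand the config into concrete queries, in config order.

    File types trusted on their own get one keyword-free query; ambiguous
    file types get one query per curated keyword.
    """
    if not config.file_types:
        raise ConfigurationError("query config lists no file types")
    queries: list[Query] = []
    for ft in config.file_types:
        if ft.keyword_required:
            if not config.keywords:
                raise ConfigurationError(f"file type {ft.ext!r} requires keywords but none configured")
            queries.extend(Query(ft.ext, kw, True) for kw in config.keywords)
        else:
            queries.append(Query(ft.ext, "", False))
    return queries


# -- raw records ------------------------------------------------------------


@dataclass
class RawFileEntry:
    name: str
    size_bytes: int
    download_url: str | None = None


@dataclass
class RawDatasetRecord:
    repository: str
    dataset_id: str
    version_tag: str
    doi: str
    title: str
    description: str
    publication_date: str
    license: str
    file_entries: list[RawFileEntry] = field(default_factory=list)


@dataclass
class ZipPreview:
    entries: list[tuple[str, int]] = field(default_factory=list)
    truncated: bool = False


# -- per-repository clients -------------------------------------------------


def _latest_version(versions: list[dict]) -> dict:
    """Newest publication date wins; ties go to the greater version tag."""

    def sort_key(v: dict) -> tuple[str, str]:
        date = (
            v.get("publication_date")
            or v.get("metadata", {}).get("publication_date")
            or v.get("published_date")
            or v.get("data", {}).get("attributes", {}).get("date_created")
            or ""
        )
        return (str(date), str(v.get("version", "")))

    ordered = sorted(versions, key=sort_key)
    best = ordered[-1]
    if len(ordered) > 1 and sort_key(ordered[-2])[0] == sort_key(best)[0]:
        log.info("version tie on publication date; keeping tag %r", best.get("version"))
    return best


class _BaseClient:
    repository: str = ""

    def search_params(self, query: Query, page: int) -> dict:
        raise NotImplementedError

    def search_page_ids(self, payload: object) -> tuple[list[str], bool]:
        """Extract (ids, has_more) from one search page payload."""
        raise NotImplementedError

    def record_params(self, dataset_id: str) -> dict:
        return {"id": dataset_id}

    def parse_record(self, payload: dict, dataset_id: str) -> RawDatasetRecord:
        raise NotImplementedError

    def preview_params(self, dataset_id: str, zip_name: str) -> dict:
        return {"id": dataset_id, "file": zip_name}

    # shared driver ---------------------------------------------------------

    def search(self, query: Query, transport: Transport) -> list[str]:
        ids: list[str] = []
        seen: set[str] = set()
        page = 1
        while True:
            try:
                payload = transport.get_json(self.repository, "search", self.search_params(query, page))
            except MdscoutError as exc:
                raise HarvestError(self.repository, f"search {query} page {page}: {exc}") from exc
            try:
                page_ids, has_more = self.search_page_ids(payload)
            except (KeyError, TypeError, AttributeError) as exc:
                raise ParseError(f"malformed {self.repository} search page {page}: {exc}") from exc
            for i in page_ids:
                if i not in seen:
                    seen.add(i)
                    ids.append(i)
            if not has_more or not page_ids:
                break
            page += 1
        return ids

    def fetch(self, dataset_id: str, transport: Transport) -> RawDatasetRecord:
        payload = transport.get_json(self.repository, "record", self.record_params(dataset_id))
        if isinstance(payload, dict) and payload.get("status") in ("deleted", "embargoed"):
            raise AccessError(f"{self.repository}/{dataset_id} is {payload['status']}")
        if isinstance(payload, dict) and "versions" in payload:
            payload = _latest_version(payload["versions"])
        try:
            return self.parse_record(payload, dataset_id)
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed {self.repository} record {dataset_id}: {exc}") from exc


class ZenodoClient(_BaseClient):
    repository = "zenodo"

    def search_params(self, query: Query, page: int) -> dict:
        q = f'filetype:"{query.file_type}"'
        if query.keyword:
            q = f'"{query.keyword}" AND {q}'
        return {"q": q, "page": page, "size": SEARCH_PAGE_SIZE}

    def search_page_ids(self, payload: object) -> tuple[list[str], bool]:
        hits = payload["hits"]  # type: ignore[index]
        ids = [str(h["id"]) for h in hits["hits"]]
        total = int(hits["total"])
        return ids, total > 0 and len(ids) == SEARCH_PAGE_SIZE

    def parse_record(self, payload: dict, dataset_id: str) -> RawDatasetRecord:
        meta = payload["metadata"]
        entries = [
            RawFileEntry(f["key"], int(f["size"]), f.get("links", {}).get("self"))
            for f in payload.get("files", [])
        ]
        return RawDatasetRecord(
            repository=self.repository,
            dataset_id=str(payload["id"]),
            version_tag=str(payload.get("version", meta.get("version", ""))),
            doi=str(payload.get("doi", "")),
            title=meta.get("title", ""),
            description=meta.get("description", ""),
            publication_date=normalize_date(meta.get("publication_date", "")),
            license=str(meta.get("license", "")),
            file_entries=entries,
        )


class FigshareClient(_BaseClient):
    repository = "figshare"

    def search_params(self, query: Query, page: int) -> dict:
        term = f":extension: {query.file_type}"
        if query.keyword:
            term = f"{query.keyword} {term}"
        return {"search_for": term, "page": page, "page_size": SEARCH_PAGE_SIZE}

    def search_page_ids(self, payload: object) -> tuple[list[str], bool]:
        ids = [str(item["id"]) for item in payload]  # type: ignore[union-attr]
        return ids, len(ids) == SEARCH_PAGE_SIZE

    def parse_record(self, payload: dict, dataset_id: str) -> RawDatasetRecord:
        lic = payload.get("license", "")
        if isinstance(lic, dict):
            lic = lic.get("name", "")
        entries = [
            RawFileEntry(f["name"], int(f["size"]), f.get("download_url"))
            for f in payload.get("files", [])
        ]
        return RawDatasetRecord(
            repository=self.repository,
            dataset_id=str(payload["id"]),
            version_tag=str(payload.get("version", "")),
            doi=str(payload.get("doi", "")),
            title=payload.get("title", ""),
            description=payload.get("description", ""),
            publication_date=normalize_date(payload.get("published_date", "")),
            license=str(lic),
            file_entries=entries,
        )


class OsfClient(_BaseClient):
    repository = "osf"

    def search_params(self, query: Query, page: int) -> dict:
        term = query.file_type
        if query.keyword:
            term = f"{query.keyword} {term}"
        return {"filter[text]": term, "page": page}

    def search_page_ids(self, payload: object) -> tuple[list[str], bool]:
        data = payload["data"]  # type: ignore[index]
        ids = [str(item["id"]) for item in data]
        has_more = bool(payload.get("links", {}).get("next"))  # type: ignore[union-attr]
        return ids, has_more

    def parse_record(self, payload: dict, dataset_id: str) -> RawDatasetRecord:
        data = payload["data"]
        attrs = data["attributes"]
        entries = [
            RawFileEntry(f["name"], int(f["size"]), f.get("download_url"))
            for f in data.get("files", [])
        ]
        return RawDatasetRecord(
            repository=self.repository,
            dataset_id=str(data["id"]),
            version_tag=str(attrs.get("version", "")),
            doi=str(attrs.get("doi", "")),
            title=attrs.get("title", ""),
            description=attrs.get("description", ""),
            publication_date=normalize_date(attrs.get("date_created", "")),
            license=str(attrs.get("license", "")),
            file_entries=entries,
        )


CLIENTS: dict[str, _BaseClient] = {
    "zenodo": ZenodoClient(),
    "figshare": FigshareClient(),
    "osf": OsfClient(),
}


def normalize_date(raw: str) -> str:
    """Repositories emit heterogeneous date formats; store plain ISO dates."""
    raw = str(raw).strip()
    if not raw:
        return ""
    # ISO timestamps -> date part; already-ISO dates pass through.
    for sep in ("T", " "):
        if sep in raw:
            raw = raw.split(sep, 1)[0]
    if len(raw) == 10 and raw[4] == "-" and raw[7] == "-":
        return raw
    # dd/mm/yyyy (Table-style dates)
    if len(raw) == 10 and raw[2] == "/" and raw[5] == "/":
        d, m, y = raw.split("/")
        return f"{y}-{m}-{d}"
    raise ParseError(f"unrecognized date format: {raw!r}")


# -- public operations ------------------------------------------------------


def search_datasets(repo: str, query: Query, transport: Transport) -> list[str]:
    """All dataset ids the repository reports for (extension, keyword).

    Traverses every result page; duplicates removed, first-seen order kept.
    """
    return CLIENTS[repo].search(query, transport)


def fetch_dataset(repo: str, dataset_id: str, transport: Transport) -> RawDatasetRecord:
    """Latest-version metadata + complete file listing for one dataset."""
    return CLIENTS[repo].fetch(dataset_id, transport)


# -- zip previews -----------------------------------------------------------


def parse_zip_preview(markup: str, repo: str) -> ZipPreview:
    """Parse the repository's HTML preview of a zip archive's content.

    Zenodo previews stop at 1000 members; a page listing exactly that many
    (or declaring more) is flagged truncated. OSF provides no preview.
    """
    if repo == "osf":
        raise UnsupportedPreviewError("OSF provides no zip preview")
    if repo not in REPOSITORIES:
        raise ConfigurationError(f"unknown repository {repo!r}")
    try:
        doc = lxml.html.fromstring(markup)
    except Exception as exc:  # lxml raises various low-level errors
        raise ParseError(f"unparseable {repo} preview: {exc}") from exc

    entries: list[tuple[str, int]] = []
    truncated = False
    if repo == "zenodo":
        rows = doc.xpath("//table[contains(@class,'preview-table')]//tr")
        for row in rows:
            cells = row.xpath("./td")
            if len(cells) < 2:
                continue  # header row
            name = cells[0].text_content().strip()
            size_text = cells[1].text_content().strip()
            try:
                entries.append((name, int(size_text)))
            except ValueError as exc:
                raise ParseError(f"bad size in zenodo preview: {size_text!r}") from exc
        if doc.xpath("//*[contains(@class,'preview-truncated')]") or len(entries) >= ZENODO_PREVIEW_LIMIT:
            truncated = True
            entries = entries[:ZENODO_PREVIEW_LIMIT]
    else:  # figshare
        items = doc.xpath("//ul[contains(@class,'file-list')]/li")
        for li in items:
            name_el = li.xpath(".//span[contains(@class,'filename')]")
            size_el = li.xpath(".//span[contains(@class,'file-size')]")
            if not name_el or not size_el:
                raise ParseError("figshare preview item missing filename/size span")
            entries.append((name_el[0].text_content().strip(), int(size_el[0].text_content().strip())))
        uls = doc.xpath("//ul[contains(@class,'file-list')]")
        if uls and uls[0].get("data-truncated") == "true":
            truncated = True
    return ZipPreview(entries=entries, truncated=truncated)


# -- selective download -----------------------------------------------------


def _download(url: str, dest: Path, transport: Transport) -> None:
    data = transport.get_bytes(url)
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    digest = hashlib.sha256(data).hexdigest()
    dest.with_suffix(dest.suffix + ".sha256").write_text(digest + "\n")


def _verify(dest: Path) -> bool:
    sumfile = dest.with_suffix(dest.suffix + ".sha256")
    if not dest.exists() or not sumfile.exists():
        return False
    actual = hashlib.sha256(dest.read_bytes()).hexdigest()
    if actual != sumfile.read_text().strip():
        raise IntegrityError(f"checksum mismatch for {dest}")
    return True


def fetch_file(entry: FileRecord, cache_dir: str | Path, transport: Transport) -> Path:
    """Download one indexed file into the cache; idempotent on re-run.

    Plain files are fetched directly. A zip member is obtained by fetching
    its archive once and extracting only the requested member, mirroring
    selective extraction from deposited archives.
    """
    cache = Path(cache_dir)
    if not entry.from_zip:
        if entry.download_url is None or not entry.download_url:
            raise ExtractionError(f"{entry.file_name} has no download url")
        dest = cache / entry.repository / entry.dataset_id / entry.file_name
        if _verify(dest):
            return dest
        _download(entry.download_url, dest, transport)
        return dest

    # zip member: archive cached once, member extracted on demand
    assert entry.origin_zip is not None
    archive_record = FileRecord(
        repository=entry.repository,
        dataset_id=entry.dataset_id,
        file_name=entry.origin_zip,
        size_bytes=0,
        download_url=entry.download_url,
    )
    archive_path = fetch_file(archive_record, cache, transport)
    dest = cache / entry.repository / entry.dataset_id / "extracted" / entry.file_name
    if dest.exists():
        return dest
    with zipfile.ZipFile(archive_path) as zf:
        if entry.file_name not in zf.namelist():
            raise ExtractionError(f"{entry.file_name!r} not in archive {entry.origin_zip!r}")
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.write_bytes(zf.read(entry.file_name))
    return dest


__all__ = [
    "Query",
    "QueryConfig",
    "FileTypeEntry",
    "RawDatasetRecord",
    "RawFileEntry",
    "ZipPreview",
    "build_queries",
    "search_datasets",
    "fetch_dataset",
    "parse_zip_preview",
    "fetch_file",
    "normalize_date",
    "extension_of",
    "REPOSITORIES",
    "ZENODO_PREVIEW_LIMIT",
]
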