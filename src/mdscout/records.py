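"""Core index records and the snapshot container.

An :class:`IndexSnapshot` is the unit of persistence of a harvest: one table
of datasets, one table of files (plain files and previewed zip members),
stored as Parquet and exportable 1:1 as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SchemaError

#: Column order of the persisted files table.
FILE_COLUMNS = [
    "repository",
    "dataset_id",
    "file_name",
    "file_extension",
    "size_bytes",
    "from_zip",
    "origin_zip",
    "download_url",
]

#: Column order of the persisted datasets table.
DATASET_COLUMNS = [
    "repository",
    "dataset_id",
    "doi",
    "title",
    "description",
    "publication_date",
    "version_tag",
    "license",
    "n_files",
    "total_size_bytes",
    "n_zip_files",
    "n_files_within_zip",
]

#: Extensions treated as zip-style archives whose content repositories preview.
ARCHIVE_EXTENSIONS = {"zip"}


def extension_of(path: str) -> str:
    """Lowercase extension of the base name, without the dot.

    Compound suffixes take the last token (``a.tar.gz`` -> ``gz``); names
    without a dot map to ``"none"``.
    """
    base = path.rsplit("/", 1)[-1]
    if "." not in base or base.endswith("."):
        return "none"
    ext = base.rsplit(".", 1)[-1].lower()
    return ext if ext else "none"


@dataclass
class FileRecord:
    """One indexed file, possibly a member of a zip archive."""

    repository: str
    dataset_id: str
    file_name: str
    size_bytes: int
    from_zip: bool = False
    origin_zip: str | None = None
    download_url: str | None = None
    file_extension: str = ""

    def __post_init__(self) -> None:
        if not self.file_extension:
            self.file_extension = extension_of(self.file_name)
        if self.from_zip != (self.origin_zip is not None):
            raise ValueError("from_zip is true iff origin_zip is present")


@dataclass
class DatasetRecord:
    """One repository dataset; aggregates are recomputed from file rows."""

    repository: str
    dataset_id: str
    doi: str
    title: str
    description: str
    publication_date: str
    version_tag: str = ""
    license: str = ""
    n_files: int = 0
    total_size_bytes: int = 0
    n_zip_files: int = 0
    n_files_within_zip: int = 0


def files_frame(records: list[FileRecord]) -> pd.DataFrame:
    rows = [
        {
            "repository": r.repository,
            "dataset_id": r.dataset_id,
            "file_name": r.file_name,
            "file_extension": r.file_extension,
            "size_bytes": int(r.size_bytes),
            "from_zip": bool(r.from_zip),
            "origin_zip": r.origin_zip if r.origin_zip is not None else "",
            "download_url": r.download_url if r.download_url is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=FILE_COLUMNS)


def datasets_frame(records: list[DatasetRecord]) -> pd.DataFrame:
    rows = [
        {
            "repository": r.repository,
            "dataset_id": r.dataset_id,
            "doi": r.doi,
            "title": r.title,
            "description": r.description,
            "publication_date": r.publication_date,
            "version_tag": r.version_tag,
            "license": r.license,
            "n_files": int(r.n_files),
            "total_size_bytes": int(r.total_size_bytes),
            "n_zip_files": int(r.n_zip_files),
            "n_files_within_zip": int(r.n_files_within_zip),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


@dataclass
class IndexSnapshot:
    """A harvest: dataset table + file table + harvest date (ISO-8601)."""

    datasets: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=DATASET_COLUMNS))
    files: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FILE_COLUMNS))
    harvest_date: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        missing_d = [c for c in DATASET_COLUMNS if c not in self.datasets.columns]
        if missing_d:
            raise SchemaError(missing_d, table="datasets")
        missing_f = [c for c in FILE_COLUMNS if c not in self.files.columns]
        if missing_f:
            raise SchemaError(missing_f, table="files")
        if self.datasets.duplicated(subset=["repository", "dataset_id"]).any():
            raise SchemaError(["repository/dataset_id must be unique"], table="datasets")

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.datasets.to_parquet(directory / "datasets.parquet", index=False)
        self.files.to_parquet(directory / "files.parquet", index=False)
        (directory / "harvest_date.txt").write_text(self.harvest_date + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "IndexSnapshot":
        directory = Path(directory)
        datasets = pd.read_parquet(directory / "datasets.parquet")
        files = pd.read_parquet(directory / "files.parquet")
        date_file = directory / "harvest_date.txt"
        harvest_date = date_file.read_text().strip() if date_file.exists() else ""
        return cls(datasets=datasets, files=files, harvest_date=harvest_date)

    def to_tsv(self, directory: str | Path) -> None:
        """Mirror both tables as TSV, columns 1:1 with the Parquet schema."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.datasets.to_csv(directory / "datasets.tsv", sep="\t", index=False)
        self.files.to_csv(directory / "files.tsv", sep="\t", index=False)
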