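"""High-level orchestration: harvest a corpus, then mine its Gromacs files.

Thin composition of the module-level operations, shared by the CLI and the
reproduction scripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import analytics, ex2
from .errors import MdscoutError
from .gromacs import parse_gro, parse_mdp, read_xtc_info_path
from .gromacs.xtc import XtcInfo
from .inference import CompositionProfile, MdpAnnotation, annotate_mdp, categorize_residues
from .records import FileRecord, IndexSnapshot
from .repo_clients import QueryConfig, build_queries, fetch_file
from .transport import Transport

log = logging.getLogger(__name__)


def run_harvest(
    repos: list[str],
    config: QueryConfig,
    transport: Transport,
    harvest_date: str | None = None,
) -> IndexSnapshot:
    """explore → expand → clean with one query config."""
    queries = build_queries(config)
    candidates = ex2.explore(repos, queries, transport)
    index = ex2.expand(candidates, transport, harvest_date=harvest_date)
    return ex2.clean(index, config.target_extensions())


def _file_records(index: IndexSnapshot, extension: str) -> list[FileRecord]:
    sub = index.files[index.files["file_extension"] == extension]
    return [
        FileRecord(
            repository=row.repository,
            dataset_id=row.dataset_id,
            file_name=row.file_name,
            size_bytes=int(row.size_bytes),
            from_zip=bool(row.from_zip),
            origin_zip=row.origin_zip or None,
            download_url=row.download_url or None,
            file_extension=row.file_extension,
        )
        for row in sub.itertuples(index=False)
    ]


@dataclass
class GromacsContent:
    """Parsed content of the harvested .gro / .mdp / sampled .xtc files."""

    profiles: list[CompositionProfile] = field(default_factory=list)
    annotations: list[MdpAnnotation] = field(default_factory=list)
    xtc_infos: dict[str, XtcInfo] = field(default_factory=dict)
    n_failed: int = 0


def annotate_gromacs_content(
    index: IndexSnapshot,
    transport: Transport,
    cache_dir: str | Path,
    *,
    sample_xtc: bool = True,
) -> GromacsContent:
    """Download and parse every indexed .gro and .mdp file (zip members
    included) plus one .xtc per dataset; unreadable files are counted and
    skipped, never fatal."""
    content = GromacsContent()
    for record in _file_records(index, "gro"):
        try:
            path = fetch_file(record, cache_dir, transport)
            content.profiles.append(categorize_residues(parse_gro(path.read_text())))
        except MdscoutError as exc:
            log.warning("unreadable .gro %s: %s", record.file_name, exc)
            content.n_failed += 1
    for record in _file_records(index, "mdp"):
        try:
            path = fetch_file(record, cache_dir, transport)
            content.annotations.append(annotate_mdp(parse_mdp(path.read_text())))
        except MdscoutError as exc:
            log.warning("unreadable .mdp %s: %s", record.file_name, exc)
            content.n_failed += 1
    if sample_xtc:
        for record in analytics.sample_one_per_dataset(index, "xtc"):
            try:
                path = fetch_file(record, cache_dir, transport)
                key = f"{record.repository}/{record.dataset_id}/{record.file_name}"
                content.xtc_infos[key] = read_xtc_info_path(str(path))
            except MdscoutError as exc:
                log.warning("unreadable .xtc %s: %s", record.file_name, exc)
                content.n_failed += 1
    return content
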