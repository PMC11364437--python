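"""Exception hierarchy.

Harvest-facing errors distinguish "the repository said no" (missing,
embargoed) from "the network said no" (transport), because a long harvest
skips the former and retries the latter.
"""

from __future__ import annotations


class MdscoutError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MdscoutError):
    """Invalid query or dictionary configuration."""


class TransportError(MdscoutError):
    """Network/transport failure after bounded retries."""


class HarvestError(MdscoutError):
    """Search or catalogue step failed for one (repository, query)."""

    def __init__(self, repository: str, detail: str):
        self.repository = repository
        self.detail = detail
        super().__init__(f"[{repository}] {detail}")


class MissingDatasetError(MdscoutError):
    """Dataset id unknown to the repository (404)."""


class AccessError(MdscoutError):
    """Dataset exists but is deleted or embargoed."""


class ParseError(MdscoutError):
    """Malformed page or file content."""


class UnsupportedPreviewError(MdscoutError):
    """Repository provides no zip-content preview (OSF)."""


class IntegrityError(MdscoutError):
    """Downloaded file does not match its recorded checksum."""


class ExtractionError(MdscoutError):
    """Requested member absent from a zip archive."""


class MergeError(MdscoutError):
    """Snapshots cannot be merged (conflicting repository enums)."""


class SchemaError(MdscoutError):
    """Snapshot table is missing required columns."""

    def __init__(self, missing: list[str], table: str = ""):
        self.missing = list(missing)
        self.table = table
        cols = ", ".join(self.missing)
        super().__init__(f"missing required column(s) in {table or 'table'}: {cols}")


class QueryError(MdscoutError):
    """Malformed search query (e.g. bad date range)."""


class GenerationError(MdscoutError):
    """Fixture corpus spec violates its invariants."""


# -- Gromacs file formats ---------------------------------------------------


class GroFormatError(ParseError):
    """.gro file violates the fixed-column format."""


class GroTruncationError(GroFormatError):
    """.gro file declares more atoms than it contains."""

    def __init__(self, expected: int, found: int):
        self.expected = expected
        self.found = found
        super().__init__(f"truncated .gro: expected {expected} atom lines, found {found}")


class NotAnXtcError(ParseError):
    """Stream does not start with the XTC magic number."""


class XtcCorruptionError(ParseError):
    """Bad magic number mid-stream."""

    def __init__(self, frame_index: int):
        self.frame_index = frame_index
        super().__init__(f"corrupt XTC frame at index {frame_index}")
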