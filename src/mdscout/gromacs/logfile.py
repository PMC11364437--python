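"""Best-effort extraction from Gromacs run logs (.log).

Run logs start with a banner naming the Gromacs version and echo the exact
command line used. Both fields degrade to absent when the patterns are not
found — never guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_VERSION_RE = re.compile(r"GROMACS\s+version:\s*(\S+)", re.IGNORECASE)
_CMDLINE_HEADER_RE = re.compile(r"^\s*Command line:\s*$", re.IGNORECASE)
_GMX_RE = re.compile(r"^\s*(gmx(?:_mpi|_d)?\s+\S.*)$")


@dataclass
class LogInfo:
    gromacs_version: str | None = None
    command_line: str | None = None


def parse_log(text: str) -> LogInfo:
    """Extract the Gromacs version and command line from run-log text."""
    info = LogInfo()
    match = _VERSION_RE.search(text)
    if match:
        info.gromacs_version = match.group(1)

    lines = text.splitlines()
    for i, line in enumerate(lines):
        if _CMDLINE_HEADER_RE.match(line) and i + 1 < len(lines):
            candidate = lines[i + 1].strip()
            if candidate:
                info.command_line = candidate
                break
    if info.command_line is None:
        for line in lines:
            match = _GMX_RE.match(line)
            if match:
                info.command_line = match.group(1).strip()
                break
    return info
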