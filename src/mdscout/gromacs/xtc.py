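"""Frame/particle counting for Gromacs .xtc trajectories.

XTC is big-endian XDR. Each frame: magic int 1995, atom count, step, time
(float), 9 box floats, then the coordinate block — the atom count repeated,
followed either by 3·n plain floats (n ≤ 9, uncompressed branch) or by the
compressed payload (precision float, 6 bounding ints, small index, byte
count, payload padded to 4 bytes).

The reader counts frames by skipping coordinate payloads without ever
decompressing them, so multi-gigabyte trajectories scan at I/O speed —
the same information ``gmx check`` reports.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import BinaryIO

from ..errors import NotAnXtcError, ParseError, XtcCorruptionError

XTC_MAGIC = 1995
#: At or below this atom count coordinates are stored as plain floats.
UNCOMPRESSED_MAX_ATOMS = 9

_INT = struct.Struct(">i")
_FLOAT = struct.Struct(">f")
_HEADER = struct.Struct(">iiif")  # magic, natoms, step, time


@dataclass
class XtcInfo:
    n_atoms: int = 0
    n_frames: int = 0
    first_time_ps: float | None = None
    last_time_ps: float | None = None
    truncated: bool = False


class _Truncated(Exception):
    """Internal: EOF inside a frame."""


def _read_exact(stream: BinaryIO, n: int) -> bytes:
    data = stream.read(n)
    if len(data) < n:
        raise _Truncated
    return data


def _skip_exact(stream: BinaryIO, n: int) -> None:
    if n == 0:
        return
    # seek when possible; fall back to chunked reads for unseekable streams
    try:
        start = stream.tell()
        stream.seek(n, 1)
        if stream.tell() - start < n:
            raise _Truncated
        # seeking past EOF does not fail; probe one byte back to confirm
        stream.seek(-1, 1)
        if stream.read(1) == b"":
            raise _Truncated
    except OSError:
        remaining = n
        while remaining > 0:
            chunk = stream.read(min(remaining, 1 << 20))
            if not chunk:
                raise _Truncated
            remaining -= len(chunk)


def _skip_frame_payload(stream: BinaryIO, n_atoms_header: int) -> None:
    """Consume the coordinate block that follows a frame header + box."""
    (n_atoms,) = _INT.unpack(_read_exact(stream, 4))
    if n_atoms != n_atoms_header:
        raise ParseError(
            f"coordinate block atom count {n_atoms} != header {n_atoms_header}"
        )
    if n_atoms <= UNCOMPRESSED_MAX_ATOMS:
        _skip_exact(stream, 4 * 3 * n_atoms)
        return
    # compressed branch: precision, minint[3], maxint[3], smallidx, nbytes
    _read_exact(stream, 4)  # precision
    _read_exact(stream, 24)  # bounding ints
    _read_exact(stream, 4)  # small index
    (nbytes,) = _INT.unpack(_read_exact(stream, 4))
    if nbytes < 0:
        raise ParseError(f"negative compressed payload size: {nbytes}")
    padded = (nbytes + 3) & ~3
    _skip_exact(stream, padded)


def read_xtc_info(stream: BinaryIO) -> XtcInfo:
    """Count atoms, frames and time span of an XTC stream.

    A trailing partial frame sets ``truncated`` and is not counted; a bad
    magic number on the very first frame means the stream is not XTC at
    all, while one mid-stream reports the corrupt frame index.
    """
    info = XtcInfo()
    frame = 0
    while True:
        head = stream.read(_HEADER.size)
        if head == b"":
            break
        if len(head) < _HEADER.size:
            info.truncated = True
            break
        magic, n_atoms, _step, time = _HEADER.unpack(head)
        if magic != XTC_MAGIC:
            if frame == 0:
                raise NotAnXtcError(f"first magic {magic} != {XTC_MAGIC}")
            raise XtcCorruptionError(frame_index=frame)
        if frame == 0:
            info.n_atoms = n_atoms
        elif n_atoms != info.n_atoms:
            raise ParseError(
                f"frame {frame} atom count {n_atoms} != frame 0 count {info.n_atoms}"
            )
        try:
            _read_exact(stream, 9 * 4)  # box
            _skip_frame_payload(stream, n_atoms)
        except _Truncated:
            info.truncated = True
            break
        if info.first_time_ps is None:
            info.first_time_ps = float(time)
        info.last_time_ps = float(time)
        frame += 1
    info.n_frames = frame
    return info


def read_xtc_info_path(path: str) -> XtcInfo:
    with open(path, "rb") as fh:
        return read_xtc_info(fh)
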