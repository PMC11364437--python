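"""Reader and writer for the Gromacs .gro fixed-column coordinate format.

Layout: a free-text title line; an atom-count line; one fixed-width line per
atom (``%5d%-5s%5s%5d`` then three ``%8.3f`` coordinates in nm, optionally
three ``%8.4f`` velocities in nm/ps); a box line of 3 or 9 reals.

Columns are sliced by character position, never split on whitespace: large
residue/atom numbers and long names routinely merge adjacent columns in
deposited files, which token splitting would misparse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..errors import GroFormatError, GroTruncationError

# character spans of the fixed-width fields
_RESID = slice(0, 5)
_RESNAME = slice(5, 10)
_ATOMNAME = slice(10, 15)
_ATOMID = slice(15, 20)
_COORD_WIDTH = 8
_COORD_START = 20
_VEL_LINE_LEN = 20 + 6 * _COORD_WIDTH  # 68: line long enough to hold velocities


@dataclass
class GroAtom:
    residue_number: int
    residue_name: str
    atom_name: str
    atom_number: int
    x: float
    y: float
    z: float
    vx: float | None = None
    vy: float | None = None
    vz: float | None = None


@dataclass
class GroSystem:
    title: str
    n_atoms: int
    atoms: list[GroAtom] = field(default_factory=list)
    box: list[float] = field(default_factory=list)

    @property
    def residue_names(self) -> list[str]:
        return [a.residue_name for a in self.atoms]

    @property
    def has_velocities(self) -> bool:
        return bool(self.atoms) and self.atoms[0].vx is not None


def _slice_float(line: str, start: int, width: int, what: str) -> float:
    text = line[start : start + width]
    try:
        value = float(text)
    except ValueError as exc:
        raise GroFormatError(f"bad {what} field {text!r}") from exc
    if not math.isfinite(value):
        raise GroFormatError(f"non-finite {what}: {text!r}")
    return value


def _slice_int(line: str, span: slice, what: str) -> int:
    text = line[span]
    try:
        return int(text)
    except ValueError as exc:
        raise GroFormatError(f"bad {what} field {text!r}") from exc


def parse_gro(text: str) -> GroSystem:
    """Parse .gro text into a :class:`GroSystem`.

    Velocity columns are detected from the line length of the first atom
    line. Declaring more atoms than the file holds raises
    :class:`GroTruncationError` with expected vs found counts.
    """
    lines = text.splitlines()
    if len(lines) < 2:
        raise GroFormatError("file shorter than title + atom-count lines")
    title = lines[0].rstrip("\n")
    count_text = lines[1].strip()
    try:
        n_atoms = int(count_text)
    except ValueError as exc:
        raise GroFormatError(f"atom-count line is not an integer: {count_text!r}") from exc
    if n_atoms < 0:
        raise GroFormatError(f"negative atom count: {n_atoms}")

    body = lines[2:]
    # the final line is the box, so a complete file holds n_atoms + 1 lines
    if len(body) < n_atoms + 1:
        raise GroTruncationError(expected=n_atoms, found=max(0, len(body) - 1))
    atom_lines = body[:n_atoms]

    atoms: list[GroAtom] = []
    for line in atom_lines:
        if len(line) < _COORD_START + 3 * _COORD_WIDTH:
            raise GroFormatError(f"atom line too short ({len(line)} chars): {line!r}")
        with_velocities = len(line.rstrip()) >= _VEL_LINE_LEN
        coords = [
            _slice_float(line, _COORD_START + i * _COORD_WIDTH, _COORD_WIDTH, "coordinate")
            for i in range(3)
        ]
        vels: list[float | None] = [None, None, None]
        if with_velocities:
            vels = [
                _slice_float(line, _COORD_START + (3 + i) * _COORD_WIDTH, _COORD_WIDTH, "velocity")
                for i in range(3)
            ]
        atoms.append(
            GroAtom(
                residue_number=_slice_int(line, _RESID, "residue number"),
                residue_name=line[_RESNAME].strip(),
                atom_name=line[_ATOMNAME].strip(),
                atom_number=_slice_int(line, _ATOMID, "atom number"),
                x=coords[0],
                y=coords[1],
                z=coords[2],
                vx=vels[0],
                vy=vels[1],
                vz=vels[2],
            )
        )

    box_line = body[n_atoms] if len(body) > n_atoms else ""
    try:
        box = [float(tok) for tok in box_line.split()]
    except ValueError as exc:
        raise GroFormatError(f"bad box line: {box_line!r}") from exc
    if len(box) not in (0, 3, 9):
        raise GroFormatError(f"box line must hold 3 or 9 reals, got {len(box)}")
    return GroSystem(title=title, n_atoms=n_atoms, atoms=atoms, box=box)


def write_gro(system: GroSystem) -> str:
    """Serialize a :class:`GroSystem` back to fixed-column text."""
    out = [system.title, f"{system.n_atoms:5d}"]
    for a in system.atoms:
        line = (
            f"{a.residue_number % 100000:5d}{a.residue_name:<5.5s}{a.atom_name:>5.5s}"
            f"{a.atom_number % 100000:5d}{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
        )
        if a.vx is not None:
            line += f"{a.vx:8.4f}{a.vy:8.4f}{a.vz:8.4f}"
        out.append(line)
    box = system.box or [0.0, 0.0, 0.0]
    out.append(" ".join(f"{v:10.5f}" for v in box))
    return "\n".join(out) + "\n"
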