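"""Total parser for Gromacs .mdp run-parameter files.

``key = value`` lines with ``;`` comments. Gromacs treats ``-`` and ``_`` in
keys interchangeably and is case-insensitive, so keys are normalized to
lowercase with underscores. The parser never raises: unparseable lines are
counted as warnings and typed fields are simply left absent when their raw
value does not parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def normalize_key(key: str) -> str:
    return key.strip().lower().replace("-", "_")


@dataclass
class MdpParameters:
    """Raw key/value mapping plus the typed fields mined downstream.

    dt is in ps, ref_t in K; ``raw`` preserves first-seen key order with
    last-occurrence values (Gromacs semantics for repeated keys).
    """

    raw: dict[str, str] = field(default_factory=dict)
    integrator: str | None = None
    dt_ps: float | None = None
    nsteps: int | None = None
    ref_t_k: list[float] | None = None
    tcoupl_raw: str | None = None
    pcoupl_raw: str | None = None
    n_warnings: int = 0


def _parse_float(text: str) -> float | None:
    try:
        return float(text)
    except ValueError:
        return None


def parse_mdp(text: str) -> MdpParameters:
    """Parse .mdp text; total on arbitrary input."""
    raw: dict[str, str] = {}
    warnings = 0
    for line in text.splitlines():
        line = line.split(";", 1)[0]  # full-line and trailing comments
        if not line.strip():
            continue
        if "=" not in line:
            warnings += 1
            continue
        key, value = line.split("=", 1)
        key = normalize_key(key)
        if not key:
            warnings += 1
            continue
        raw[key] = value.strip()

    params = MdpParameters(raw=raw, n_warnings=warnings)
    if "integrator" in raw:
        params.integrator = raw["integrator"].strip().lower() or None
    if "dt" in raw:
        dt = _parse_float(raw["dt"])
        if dt is not None and dt > 0:
            params.dt_ps = dt
    if "nsteps" in raw:
        nsteps = _parse_float(raw["nsteps"])  # Gromacs accepts e.g. 5e5
        if nsteps is not None and nsteps >= 0 and float(nsteps).is_integer():
            params.nsteps = int(nsteps)
    if "ref_t" in raw:
        values = [_parse_float(tok) for tok in raw["ref_t"].split()]
        if values and all(v is not None for v in values):
            params.ref_t_k = [float(v) for v in values]  # type: ignore[arg-type]
    if "tcoupl" in raw:
        params.tcoupl_raw = raw["tcoupl"]
    if "pcoupl" in raw:
        params.pcoupl_raw = raw["pcoupl"]
    return params
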