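"""Derived annotations: engine assignment, molecular composition, simulation
time, model resolution, canonical coupling algorithms, headline temperature.

Classification rules follow Gromacs conventions: simulation time is
dt × nsteps; a time step of 10 fs or more marks a coarse-grained setup
(no atomistic force field integrates that coarsely, while Martini-style
models routinely use 20–30 fs); thermostat/barostat strings are normalized
against the option values the Gromacs documentation defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files
from pathlib import Path

import yaml

from .gromacs.gro import GroSystem
from .gromacs.mdp import MdpParameters, normalize_key

ENGINES = ("gromacs", "amber", "namd/charmm", "desmond", "unknown")

CATEGORIES = ("protein", "lipid", "nucleic", "glucid", "water_ions", "other")

#: Time step (ps) at and above which a setup is classified coarse-grain.
CG_DT_CUTOFF_PS = 0.01

#: Integrators that correspond to actual dynamics (vs minimization etc.).
PRODUCTION_INTEGRATORS = {"md", "sd"}

#: Minimum simulation time (ns) for the production-run filter.
PRODUCTION_MIN_TIME_NS = 1.0

#: Thermostat option values defined by the Gromacs documentation.
KNOWN_THERMOSTATS = {"no", "berendsen", "nose-hoover", "andersen", "andersen-massive", "v-rescale"}

#: Barostat option values defined by the Gromacs documentation.
KNOWN_BAROSTATS = {"no", "berendsen", "c-rescale", "parrinello-rahman", "mttk"}


def _load_yaml(resource: str, override: str | Path | None) -> dict:
    if override is not None:
        return yaml.safe_load(Path(override).read_text())
    return yaml.safe_load((files("mdscout.data") / resource).read_text())


@lru_cache(maxsize=None)
def default_engine_table() -> dict[str, str]:
    return load_engine_table(None)


def load_engine_table(path: str | Path | None) -> dict[str, str]:
    """Extension -> engine mapping (data file, overridable)."""
    raw = _load_yaml("engines.yml", path)
    table: dict[str, str] = {}
    for engine, extensions in raw.items():
        for ext in extensions:
            table[str(ext).lower()] = str(engine)
    return table


@lru_cache(maxsize=None)
def default_residue_dictionary() -> dict[str, str]:
    return load_residue_dictionary(None)


def load_residue_dictionary(path: str | Path | None) -> dict[str, str]:
    """Uppercase residue name -> category mapping (data file, overridable)."""
    raw = _load_yaml("residues.yml", path)
    mapping: dict[str, str] = {}
    for category, names in raw.items():
        if category not in CATEGORIES:
            raise ValueError(f"unknown residue category {category!r}")
        for name in names:
            mapping[str(name).upper()] = category
    return mapping


def assign_engine(extension: str, table: dict[str, str] | None = None) -> str:
    """Map a lowercase file extension to its MD engine ('unknown' if none)."""
    if table is None:
        table = default_engine_table()
    return table.get(extension.lower(), "unknown")


# -- molecular composition --------------------------------------------------


@dataclass
class CompositionProfile:
    """Per-category atom census of one coordinate file."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def group_label(self) -> str:
        """Composition group for upset-style counting.

        Water and ions are solvent background: they never define a group.
        Systems holding only water/ions are their own class; systems with
        nothing recognizable (or nothing at all) are "other".
        """
        present = sorted(c for c in CATEGORIES if c not in ("water_ions",) and self.counts[c] > 0)
        if present:
            return "+".join(present)
        if self.counts["water_ions"] > 0:
            return "water/ions only"
        return "other"


def categorize_residues(
    system: GroSystem, dictionary: dict[str, str] | None = None
) -> CompositionProfile:
    """Census of atoms per molecular category via residue-name lookup.

    Lookup is case-insensitive on stripped names; unmatched residues count
    as "other". Counts always sum to the system's atom count.
    """
    if dictionary is None:
        dictionary = default_residue_dictionary()
    profile = CompositionProfile()
    for atom in system.atoms:
        category = dictionary.get(atom.residue_name.strip().upper(), "other")
        profile.counts[category] += 1
    return profile


# -- .mdp-derived annotations -----------------------------------------------


def simulation_time(mdp: MdpParameters) -> float | None:
    """Planned simulation time in ns: dt(ps) × nsteps / 1000; absent if either is."""
    if mdp.dt_ps is None or mdp.nsteps is None:
        return None
    return mdp.dt_ps * mdp.nsteps / 1000.0


def resolution_class(mdp: MdpParameters) -> str:
    """'coarse-grain' at dt ≥ 10 fs, 'all-atom' below, 'unknown' without dt."""
    if mdp.dt_ps is None:
        return "unknown"
    return "coarse-grain" if mdp.dt_ps >= CG_DT_CUTOFF_PS else "all-atom"


def normalize_coupling(raw: str | None, kind: str) -> str:
    """Canonical thermostat/barostat value, 'none', or 'invalid'.

    Matching is case-insensitive and treats '-'/'_' interchangeably, like
    Gromacs itself; values outside the documented option lists are kept as
    'invalid' so downstream analytics can exclude them.
    """
    if kind == "thermostat":
        known = KNOWN_THERMOSTATS
    elif kind == "barostat":
        known = KNOWN_BAROSTATS
    else:
        raise ValueError(f"kind must be thermostat or barostat, got {kind!r}")
    if raw is None or not raw.strip():
        return "none"
    canonical = normalize_key(raw).replace("_", "-")
    if canonical == "no":
        return "none"
    return canonical if canonical in known else "invalid"


def headline_temperature(mdp: MdpParameters, rule: str = "first") -> float | None:
    """One temperature (K) per file from the per-group ref_t list.

    Coupling groups nearly always share one reference temperature; the
    default takes the first group. 'max' and 'mean' are available for
    sensitivity checks.
    """
    if not mdp.ref_t_k:
        return None
    if rule == "first":
        return mdp.ref_t_k[0]
    if rule == "max":
        return max(mdp.ref_t_k)
    if rule == "mean":
        return sum(mdp.ref_t_k) / len(mdp.ref_t_k)
    raise ValueError(f"unknown headline-temperature rule {rule!r}")


def is_production_candidate(mdp: MdpParameters) -> bool:
    """md/sd integrator with over 1 ns of planned time — excludes most
    minimization and equilibration setups."""
    if mdp.integrator not in PRODUCTION_INTEGRATORS:
        return False
    time_ns = simulation_time(mdp)
    return time_ns is not None and time_ns > PRODUCTION_MIN_TIME_NS


@dataclass
class MdpAnnotation:
    """Everything mined from one .mdp file."""

    simulation_time_ns: float | None
    resolution: str
    thermostat: str
    barostat: str
    temperature_k: float | None
    is_production_candidate: bool


def annotate_mdp(mdp: MdpParameters, temperature_rule: str = "first") -> MdpAnnotation:
    return MdpAnnotation(
        simulation_time_ns=simulation_time(mdp),
        resolution=resolution_class(mdp),
        thermostat=normalize_coupling(mdp.tcoupl_raw, "thermostat"),
        barostat=normalize_coupling(mdp.pcoupl_raw, "barostat"),
        temperature_k=headline_temperature(mdp, temperature_rule),
        is_production_candidate=is_production_candidate(mdp),
    )
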