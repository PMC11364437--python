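"""Synthetic repository corpora with known ground truth.

Generates everything a harvest touches — search-API pages, dataset records,
zip-preview HTML in each repository's dialect, and real downloadable
Gromacs files (including zip archives) — plus a :class:`Manifest` holding
the value every analytics operation must report on that corpus.

The manifest is the brute-force oracle: it is computed here by direct
enumeration over the planted truth (template labels, drawn parameters,
private copies of the classification tables), never by calling the
indexing, parsing or analytics code paths it validates.

Default draw distributions emulate the observed statistical structure of
deposited MD data: a Gromacs-dominated engine mixture, all-atom time steps
of 1–4 fs vs coarse-grain steps of 10–30 fs (with coarse-grain setups
dominating the longest planned simulations), starting temperatures peaked
at 298–310 K with minor mass from 100 to 800 K, and zip-heavy datasets in
which archive members outnumber plain files roughly sevenfold.
"""

from __future__ import annotations

import io
import json
import math
import random
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GenerationError
from .repo_clients import SEARCH_PAGE_SIZE, Query, QueryConfig, build_queries
from .transport import FixtureWriter

# -- private classification tables (manifest-side copies) -------------------
# Deliberately duplicated from the package data files so the manifest never
# depends on the code paths under test.

_ENGINE_TABLE = {
    **{e: "gromacs" for e in ("gro", "mdp", "xtc", "trr", "tpr", "itp", "top", "edr", "ndx", "cpt")},
    **{e: "amber" for e in ("prmtop", "parm7", "inpcrd", "rst7", "mdcrd", "frcmod")},
    **{e: "namd/charmm" for e in ("psf", "dcd", "prm", "rtf", "str", "coor", "vel", "xsc")},
    **{e: "desmond" for e in ("cms", "mae")},
}

_CG_CUTOFF_PS = 0.01
_BAND_LABELS = ("(1, 50] ns", "(50, 1000] ns", "> 1000 ns")


def _ext_of(name: str) -> str:
    base = name.rsplit("/", 1)[-1]
    if "." not in base or base.endswith("."):
        return "none"
    return base.rsplit(".", 1)[-1].lower()


# -- composition templates --------------------------------------------------
# (label, [(residue_name, n_residues_lo, n_residues_hi, atoms_per_residue)])
_COMPOSITIONS: list[tuple[str, list[tuple[str, int, int, int]]]] = [
    ("protein", [("ALA", 2, 6, 5), ("GLY", 1, 4, 4), ("SOL", 4, 12, 3)]),
    ("lipid+protein", [("ALA", 2, 5, 5), ("POPC", 2, 6, 10), ("SOL", 4, 10, 3)]),
    ("lipid", [("POPC", 2, 8, 10), ("W", 3, 9, 1)]),
    ("nucleic+protein", [("ARG", 2, 5, 7), ("DA", 2, 5, 6), ("SOL", 3, 8, 3), ("NA", 1, 3, 1)]),
    ("nucleic", [("DG", 2, 6, 6), ("SOL", 3, 8, 3)]),
    ("water/ions only", [("SOL", 5, 15, 3), ("NA", 1, 3, 1), ("CL", 1, 3, 1)]),
    ("other", [("XYZ", 2, 8, 4)]),
    ("glucid+protein", [("GLC", 1, 4, 8), ("ALA", 2, 5, 5), ("SOL", 3, 8, 3)]),
]
_COMPOSITION_WEIGHTS = [0.28, 0.20, 0.18, 0.08, 0.07, 0.06, 0.08, 0.05]

# thermostat/barostat draws: (spelled value or None, canonical)
_THERMOSTATS = [
    ("V-rescale", "v-rescale"),
    ("v_rescale", "v-rescale"),
    ("Berendsen", "berendsen"),
    ("Nose-Hoover", "nose-hoover"),
    ("Nose_Hoover", "nose-hoover"),
    ("no", "none"),
    (None, "none"),
    ("dummy-stat", "invalid"),
]
_THERMOSTAT_WEIGHTS = [0.34, 0.08, 0.14, 0.12, 0.04, 0.08, 0.16, 0.04]
_BAROSTATS = [
    ("Parrinello-Rahman", "parrinello-rahman"),
    ("parrinello_rahman", "parrinello-rahman"),
    ("Berendsen", "berendsen"),
    ("C-rescale", "c-rescale"),
    ("no", "none"),
    (None, "none"),
    ("MyBaro", "invalid"),
]
_BAROSTAT_WEIGHTS = [0.32, 0.08, 0.18, 0.08, 0.10, 0.20, 0.04]

_KEYWORD_TITLES = [
    "Molecular dynamics of {x}",
    "Gromacs simulation files for {x}",
    "Martini coarse-grain model of {x}",
    "MD simulation trajectories: {x}",
]
_PLAIN_TITLES = [
    "Supplementary simulation data for {x}",
    "Trajectory archive: {x}",
]
_SUBJECTS = [
    "a membrane protein",
    "POPC bilayers",
    "T4 lysozyme mutants",
    "a DNA duplex",
    "solvated ubiquitin",
    "an ionic liquid",
    "lipid nanoparticles",
    "a polymer melt",
]


# -- file-content generators ------------------------------------------------


def gen_gro(
    composition: list[tuple[str, int, int]],
    seed: int,
    *,
    title: str = "synthetic system",
    velocities: bool = False,
) -> str:
    """Fixed-column .gro text for (residue_name, n_residues, atoms_per_residue).

    Coordinates are uniform in a 5 nm cubic box, written at the format's
    3-decimal precision. Independent of the package's .gro writer.
    """
    rng = random.Random(seed)
    vrng = random.Random(seed ^ 0x5EED)  # separate stream: velocity twin keeps coordinates
    lines = [title]
    n_atoms = sum(n * apr for _, n, apr in composition)
    if any(n < 0 or apr < 0 for _, n, apr in composition):
        raise GenerationError("negative residue/atom counts")
    lines.append(f"{n_atoms:5d}")
    atom_id = 0
    res_id = 0
    for resname, n_res, atoms_per in composition:
        for _ in range(n_res):
            res_id += 1
            for j in range(atoms_per):
                atom_id += 1
                x, y, z = (round(rng.uniform(0.0, 5.0), 3) for _ in range(3))
                line = (
                    f"{res_id % 100000:5d}{resname:<5.5s}{('A' + str(j + 1)):>5.5s}"
                    f"{atom_id % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
                )
                if velocities:
                    vx, vy, vz = (round(vrng.uniform(-1.0, 1.0), 4) for _ in range(3))
                    line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
                lines.append(line)
    lines.append(f"{5.0:10.5f}{5.0:10.5f}{5.0:10.5f}")
    return "\n".join(lines) + "\n"


def _spell(rng: random.Random, key: str) -> str:
    """Randomize case and '-'/'_' spelling of an .mdp key."""
    key = key.replace("_", rng.choice("-_"))
    if rng.random() < 0.3:
        key = key.upper() if rng.random() < 0.5 else key.capitalize()
    return key


def gen_mdp(params: dict[str, object], seed: int) -> str:
    """.mdp text with randomized comments, case, and '-'/'_' spellings.

    ``params`` may hold any subset of integrator, dt, nsteps, ref_t,
    tcoupl, pcoupl (values already spelled as desired).
    """
    rng = random.Random(seed)
    lines = ["; synthetic run parameters"]
    for key, value in params.items():
        if value is None:
            continue
        if isinstance(value, list):
            value = " ".join(str(v) for v in value)
        entry = f"{_spell(rng, key)} {' ' * rng.randint(0, 3)}= {value}"
        if rng.random() < 0.3:
            entry += " ; " + rng.choice(["comment", "two tc groups", "check me"])
        lines.append(entry)
        if rng.random() < 0.2:
            lines.append("; interleaved comment")
    return "\n".join(lines) + "\n"


def gen_log(version: str, command: str, seed: int) -> str:
    rng = random.Random(seed)
    return (
        f"Log file opened on 2022-0{rng.randint(1, 9)}-1{rng.randint(0, 9)}\n"
        f"GROMACS version:    {version}\n"
        "Executable:   /usr/local/gromacs/bin/gmx\n"
        "\n"
        "Command line:\n"
        f"  {command}\n"
        "\n"
        "Reading file topol.tpr\n"
    )


def gen_xtc(n_atoms: int, times: list[float], seed: int, *, truncate_tail: int = 0) -> bytes:
    """Big-endian XDR trajectory bytes in the uncompressed (≤ 9 atom) branch.

    ``truncate_tail`` drops that many bytes from the end to emulate an
    interrupted upload. Independent of the package's XTC reader.
    """
    if n_atoms > 9:
        raise GenerationError("only the uncompressed branch (n_atoms <= 9) is writable")
    if n_atoms < 0:
        raise GenerationError("negative atom count")
    rng = random.Random(seed)
    out = io.BytesIO()
    for step, time in enumerate(times):
        out.write(struct.pack(">iiif", 1995, n_atoms, step, float(time)))
        box = [5.0, 0.0, 0.0, 0.0, 5.0, 0.0, 0.0, 0.0, 5.0]
        out.write(struct.pack(">9f", *box))
        out.write(struct.pack(">i", n_atoms))
        coords = [rng.uniform(0.0, 5.0) for _ in range(3 * n_atoms)]
        if coords:
            out.write(struct.pack(f">{len(coords)}f", *coords))
    data = out.getvalue()
    return data[: len(data) - truncate_tail] if truncate_tail else data


# -- corpus spec ------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Shape of one synthetic corpus; same seed ⇒ byte-identical tree."""

    seed: int = 0
    n_datasets: dict[str, int] = field(
        default_factory=lambda: {"zenodo": 7, "figshare": 5, "osf": 3}
    )
    n_decoys: dict[str, int] = field(
        default_factory=lambda: {"zenodo": 1, "figshare": 1, "osf": 1}
    )
    #: members per zip ≈ zip_member_factor × plain file count (zip-heavy corpora)
    zip_member_factor: int = 7
    query_config: QueryConfig | None = None

    def validate(self) -> None:
        for repo, n in self.n_datasets.items():
            if repo not in ("zenodo", "figshare", "osf"):
                raise GenerationError(f"unknown repository {repo!r}")
            if n < 0 or self.n_decoys.get(repo, 0) < 0:
                raise GenerationError("dataset counts must be non-negative")
            if self.n_decoys.get(repo, 0) > n:
                raise GenerationError(f"more decoys than datasets for {repo}")


@dataclass
class Manifest:
    """Ground truth: what a correct pipeline must report on the corpus."""

    discovered: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    table1: dict[str, dict] = field(default_factory=dict)
    engine_counts: dict[str, int] = field(default_factory=dict)
    extension_counts_unknown: dict[str, int] = field(default_factory=dict)
    composition_groups: dict[str, int] = field(default_factory=dict)
    coupling_pairs: dict[str, int] = field(default_factory=dict)
    time_bands: dict[str, int] = field(default_factory=dict)
    cg_share_above_1us: float | None = None
    n_production_mdp: int = 0
    temperature_histogram_10k: dict[str, int] = field(default_factory=dict)
    n_gro_files: int = 0
    n_mdp_files: int = 0
    xtc_truth: dict[str, list[int]] = field(default_factory=dict)  # path -> [n_atoms, n_frames]

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        payload["coupling_pairs"] = {k: v for k, v in sorted(self.coupling_pairs.items())}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        return cls(**json.loads(text))


# -- internal planted structures --------------------------------------------


@dataclass
class _PlantedFile:
    name: str
    content: bytes
    in_zip: str | None = None  # archive name when a member
    gro_label: str | None = None  # composition group for .gro files
    mdp_truth: dict | None = None  # canonical planted parameters for .mdp files
    xtc_truth: tuple[int, int] | None = None  # (n_atoms, n_frames)


@dataclass
class _PlantedDataset:
    repo: str
    dataset_id: str
    title: str
    description: str
    date: str
    doi: str
    version: str
    is_decoy: bool
    files: list[_PlantedFile] = field(default_factory=list)

    @property
    def plain_files(self) -> list[_PlantedFile]:
        return [f for f in self.files if f.in_zip is None]

    @property
    def member_files(self) -> list[_PlantedFile]:
        return [f for f in self.files if f.in_zip is not None]


def _draw_mdp_truth(rng: random.Random) -> dict:
    """Draw canonical .mdp parameters; the spelled file is derived later."""
    integrator = rng.choices(["md", "sd", "steep", "cg"], weights=[0.55, 0.15, 0.2, 0.1])[0]
    coarse = rng.random() < 0.30
    dt = rng.choice([0.01, 0.02, 0.03]) if coarse else rng.choice([0.001, 0.002, 0.004])
    if integrator in ("md", "sd"):
        if coarse:
            band = rng.choices(["sub", "short", "mid", "long"], weights=[0.1, 0.3, 0.25, 0.35])[0]
        else:
            band = rng.choices(["sub", "short", "mid", "long"], weights=[0.2, 0.6, 0.15, 0.05])[0]
    else:
        band = "sub"
    time_ns = {
        "sub": rng.uniform(0.01, 0.9),
        "short": rng.uniform(1.5, 49.0),
        "mid": rng.uniform(51.0, 990.0),
        "long": rng.uniform(1100.0, 20000.0),
    }[band]
    nsteps = max(1, round(time_ns * 1000.0 / dt))
    has_temp = rng.random() < 0.85
    if has_temp:
        kind = rng.choices(["ambient", "cold", "hot"], weights=[0.8, 0.1, 0.1])[0]
        temp = {
            "ambient": rng.choice([298.0, 300.0, 303.0, 310.0]),
            "cold": float(rng.randrange(100, 280, 10)),
            "hot": rng.choice([400.0, 600.0, 800.0]),
        }[kind]
        n_groups = rng.choice([1, 2])
        ref_t = [temp] * n_groups
    else:
        ref_t = None
    if integrator in ("steep", "cg"):
        t_spelled, t_canon = (None, "none") if rng.random() < 0.7 else ("no", "none")
        p_spelled, p_canon = (None, "none")
    else:
        t_spelled, t_canon = rng.choices(_THERMOSTATS, weights=_THERMOSTAT_WEIGHTS)[0]
        p_spelled, p_canon = rng.choices(_BAROSTATS, weights=_BAROSTAT_WEIGHTS)[0]
    return {
        "integrator": integrator,
        "dt": dt,
        "nsteps": nsteps,
        "ref_t": ref_t,
        "tcoupl_spelled": t_spelled,
        "tcoupl": t_canon,
        "pcoupl_spelled": p_spelled,
        "pcoupl": p_canon,
    }


def _mdp_file(rng: random.Random, name: str, in_zip: str | None) -> _PlantedFile:
    truth = _draw_mdp_truth(rng)
    params: dict[str, object] = {
        "integrator": truth["integrator"],
        "dt": truth["dt"],
        "nsteps": truth["nsteps"],
    }
    if truth["ref_t"] is not None:
        params["ref_t"] = [f"{t:g}" for t in truth["ref_t"]]
    if truth["tcoupl_spelled"] is not None:
        params["tcoupl"] = truth["tcoupl_spelled"]
    if truth["pcoupl_spelled"] is not None:
        params["pcoupl"] = truth["pcoupl_spelled"]
    text = gen_mdp(params, seed=rng.randrange(2**31))
    return _PlantedFile(name=name, content=text.encode(), in_zip=in_zip, mdp_truth=truth)


def _gro_file(rng: random.Random, name: str, in_zip: str | None) -> _PlantedFile:
    label, template = rng.choices(_COMPOSITIONS, weights=_COMPOSITION_WEIGHTS)[0]
    composition = [(res, rng.randint(lo, hi), apr) for res, lo, hi, apr in template]
    text = gen_gro(
        composition,
        seed=rng.randrange(2**31),
        title=f"synthetic {label} system",
        velocities=rng.random() < 0.3,
    )
    return _PlantedFile(name=name, content=text.encode(), in_zip=in_zip, gro_label=label)


def _xtc_file(rng: random.Random, name: str) -> _PlantedFile:
    n_atoms = rng.randint(2, 9)
    n_frames = rng.randint(1, 8)
    times = [i * 10.0 for i in range(n_frames)]
    data = gen_xtc(n_atoms, times, seed=rng.randrange(2**31))
    return _PlantedFile(name=name, content=data, xtc_truth=(n_atoms, n_frames))


def _misc_file(rng: random.Random, in_zip: str | None, tag: str = "") -> _PlantedFile:
    name = rng.choice(
        ["notes.txt", "analysis.dat", "plot.xvg", "figure.png", "structure.pdb", "README", "energy.out"]
    )
    stem, dot, ext = name.partition(".")
    stem = f"{stem}{tag}_{rng.randrange(1000)}"
    name = f"{stem}{dot}{ext}" if dot else stem
    return _PlantedFile(name=name, content=b"synthetic filler\n", in_zip=in_zip)


def _plant_dataset(
    rng: random.Random, repo: str, index: int, is_decoy: bool, zip_factor: int = 7
) -> _PlantedDataset:
    dataset_id = {
        "zenodo": str(1000000 + index),
        "figshare": str(20000000 + index),
        "osf": f"os{index:03d}x",
    }[repo]
    subject = rng.choice(_SUBJECTS)
    date = f"{rng.randint(2013, 2023)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    ds = _PlantedDataset(
        repo=repo,
        dataset_id=dataset_id,
        title="",
        description=f"Deposited dataset with simulation output for {subject}.",
        date=date,
        doi=f"10.5072/{repo}.{dataset_id}",
        version=f"v{rng.randint(1, 3)}",
        is_decoy=is_decoy,
    )
    if is_decoy:
        ds.title = f"Molecular dynamics teaching slides on {subject}"
        archive = f"slides{rng.randrange(100)}.zip"
        ds.files.append(_PlantedFile(name=archive, content=b""))  # archive bytes built later
        for i in range(rng.randint(2, 4)):
            ds.files.append(
                _PlantedFile(name=f"slide{i}.{rng.choice(['docx', 'png', 'pptx'])}",
                             content=b"decoy\n", in_zip=archive)
            )
        ds.files.append(_misc_file(rng, None))
        return ds

    zip_only = repo != "osf" and rng.random() < 0.25
    template = rng.choice(_KEYWORD_TITLES if (zip_only or rng.random() < 0.7) else _PLAIN_TITLES)
    ds.title = template.format(x=subject)

    if zip_only:
        archive = f"simulation{rng.randrange(100)}.zip"
        ds.files.append(_PlantedFile(name=archive, content=b""))
        ds.files.append(_misc_file(rng, None))
        n_members = rng.randint(10, 2 * zip_factor + 4)
        for i in range(n_members):
            kind = rng.choices(["gro", "mdp", "misc"], weights=[0.35, 0.35, 0.3])[0]
            if kind == "gro":
                ds.files.append(_gro_file(rng, f"run{i}/conf{i}.gro", archive))
            elif kind == "mdp":
                ds.files.append(_mdp_file(rng, f"run{i}/prod{i}.mdp", archive))
            else:
                ds.files.append(_misc_file(rng, archive, tag=f"m{i}"))
        return ds

    # plain-rich dataset
    n_plain_md = rng.randint(1, 3)
    for i in range(n_plain_md):
        kind = rng.choices(["gro", "mdp", "xtc"], weights=[0.35, 0.45, 0.2])[0]
        if kind == "gro":
            ds.files.append(_gro_file(rng, f"system{i}.gro", None))
        elif kind == "mdp":
            ds.files.append(_mdp_file(rng, f"prod{i}.mdp", None))
        else:
            ds.files.append(_xtc_file(rng, f"traj{i}.xtc"))
    if rng.random() < 0.4:
        ds.files.append(
            _PlantedFile(
                name=f"run{rng.randrange(10)}.log",
                content=gen_log("2021.4", "gmx mdrun -deffnm prod", rng.randrange(2**31)).encode(),
            )
        )
    if rng.random() < 0.3:  # other-engine files keep the engine mixture realistic
        other = rng.choice(["system.psf", "traj.dcd", "complex.prmtop", "model.cms"])
        ds.files.append(_PlantedFile(name=other, content=b"other engine\n"))
    for j in range(rng.randint(0, 2)):
        ds.files.append(_misc_file(rng, None, tag=f"p{j}"))

    if repo != "osf" and rng.random() < 0.6:
        archive = f"data{rng.randrange(100)}.zip"
        ds.files.append(_PlantedFile(name=archive, content=b""))
        n_members = self_zip_members(rng, len(ds.plain_files), zip_factor)
        for i in range(n_members):
            kind = rng.choices(["gro", "mdp", "itp", "misc"], weights=[0.3, 0.3, 0.2, 0.2])[0]
            if kind == "gro":
                ds.files.append(_gro_file(rng, f"inputs/conf{i}.gro", archive))
            elif kind == "mdp":
                ds.files.append(_mdp_file(rng, f"inputs/step{i}.mdp", archive))
            elif kind == "itp":
                ds.files.append(_PlantedFile(name=f"toppar/mol{i}.itp", content=b"[ moleculetype ]\n", in_zip=archive))
            else:
                ds.files.append(_misc_file(rng, archive, tag=f"m{i}"))
    return ds


def self_zip_members(rng: random.Random, n_plain: int, factor: int = 7) -> int:
    """Member count keeping the corpus ~factor× heavier inside archives.

    Only part of the datasets carry archives (and OSF members stay
    invisible), so per-archive member counts are doubled relative to the
    factor to land the corpus-wide members:plain ratio near the target.
    """
    return max(2, 2 * factor * max(1, n_plain) + rng.randint(-2, 2))


# -- corpus assembly --------------------------------------------------------

_ZIP_STAMP = (2020, 1, 1, 0, 0, 0)  # fixed member timestamps keep trees byte-identical


def _build_zip(members: list[_PlantedFile]) -> bytes:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_STORED) as zf:
        for m in members:
            info = zipfile.ZipInfo(m.name, date_time=_ZIP_STAMP)
            zf.writestr(info, m.content)
    return buf.getvalue()


def _query_hits(ds: _PlantedDataset, query: Query) -> bool:
    """Repository search semantics: plain file names indexed, zip members not."""
    if not any(_ext_of(f.name) == query.file_type for f in ds.plain_files):
        return False
    if not query.keyword:
        return True
    return query.keyword.lower() in (ds.title + " " + ds.description).lower()


def _record_payload(ds: _PlantedDataset, urls: dict[str, str]) -> dict:
    entries = [
        {"name": f.name, "size": len(f.content), "download_url": urls[f.name]}
        for f in ds.plain_files
    ]
    if ds.repo == "zenodo":
        return {
            "id": ds.dataset_id,
            "doi": ds.doi,
            "version": ds.version,
            "metadata": {
                "title": ds.title,
                "description": ds.description,
                "publication_date": ds.date,
                "license": "cc-by-4.0",
            },
            "files": [
                {"key": e["name"], "size": e["size"], "links": {"self": e["download_url"]}}
                for e in entries
            ],
        }
    if ds.repo == "figshare":
        return {
            "id": ds.dataset_id,
            "doi": ds.doi,
            "version": ds.version,
            "title": ds.title,
            "description": ds.description,
            "published_date": ds.date + "T10:00:00Z",
            "license": {"name": "CC BY 4.0"},
            "files": entries,
        }
    return {
        "data": {
            "id": ds.dataset_id,
            "attributes": {
                "title": ds.title,
                "description": ds.description,
                "date_created": ds.date + "T00:00:00",
                "version": ds.version,
                "doi": ds.doi,
                "license": "CC-BY-4.0",
            },
            "files": entries,
        }
    }


def _preview_html(repo: str, members: list[_PlantedFile]) -> str:
    if repo == "zenodo":
        rows = "\n".join(
            f"  <tr><td>{m.name}</td><td>{len(m.content)}</td></tr>" for m in members
        )
        return (
            "<html><body>\n<table class=\"preview-table\">\n"
            "  <tr><th>Name</th><th>Size</th></tr>\n"
            f"{rows}\n</table>\n</body></html>\n"
        )
    items = "\n".join(
        f"  <li><span class=\"filename\">{m.name}</span>"
        f"<span class=\"file-size\">{len(m.content)}</span></li>"
        for m in members
    )
    return f"<html><body>\n<ul class=\"file-list\">\n{items}\n</ul>\n</body></html>\n"


def _write_search_pages(writer: FixtureWriter, repo: str, query: Query, hits: list[str]) -> None:
    from .repo_clients import CLIENTS

    client = CLIENTS[repo]
    pages = [hits[i : i + SEARCH_PAGE_SIZE] for i in range(0, len(hits), SEARCH_PAGE_SIZE)] or [[]]
    if len(hits) > 0 and len(hits) % SEARCH_PAGE_SIZE == 0:
        pages.append([])  # clients in count-based dialects probe one page past a full page
    for page_no, ids in enumerate(pages, start=1):
        if repo == "zenodo":
            payload: object = {"hits": {"hits": [{"id": i} for i in ids], "total": len(hits)}}
        elif repo == "figshare":
            payload = [{"id": i} for i in ids]
        else:
            has_next = page_no < len(pages)
            payload = {"data": [{"id": i} for i in ids], "links": {"next": "next" if has_next else None}}
        writer.record(repo, "search", client.search_params(query, page_no), payload)
    if repo == "osf" and len(hits) > 0 and len(hits) % SEARCH_PAGE_SIZE == 0:
        pass  # osf uses links.next; no probe page needed


def _visible_files(ds: _PlantedDataset) -> list[_PlantedFile]:
    """Files a harvest can catalogue: OSF zip members stay invisible."""
    if ds.repo == "osf":
        return ds.plain_files
    return ds.files


def _enumerate_manifest(
    datasets: list[_PlantedDataset], queries: list[Query], target_extensions: set[str]
) -> Manifest:
    manifest = Manifest()
    discovered = [ds for ds in datasets if any(_query_hits(ds, q) for q in queries)]
    kept: list[_PlantedDataset] = []
    for ds in discovered:
        if any(_ext_of(f.name) in target_extensions for f in _visible_files(ds)):
            kept.append(ds)
    key = lambda d: f"{d.repo}/{d.dataset_id}"
    manifest.discovered = sorted(key(d) for d in discovered)
    manifest.kept = sorted(key(d) for d in kept)
    manifest.removed = sorted(set(manifest.discovered) - set(manifest.kept))

    # Table-1-style per-repository summary over kept datasets
    repos = sorted({d.repo for d in kept})
    total = {
        "n_datasets": 0, "n_files": 0, "total_size_gb": 0.0,
        "n_zip_files": 0, "n_files_within_zip": 0, "n_total_files": 0,
        "first_dataset_date": "", "latest_dataset_date": "",
    }
    all_dates: list[str] = []
    for repo in repos:
        sub = [d for d in kept if d.repo == repo]
        dates = sorted(d.date for d in sub)
        n_files = sum(len(d.plain_files) for d in sub)
        n_members = sum(len(d.member_files) if d.repo != "osf" else 0 for d in sub)
        row = {
            "n_datasets": len(sub),
            "first_dataset_date": dates[0],
            "latest_dataset_date": dates[-1],
            "n_files": n_files,
            "total_size_gb": sum(len(f.content) for d in sub for f in d.plain_files) / 1e9,
            "n_zip_files": sum(
                1 for d in sub for f in d.plain_files if _ext_of(f.name) == "zip"
            ),
            "n_files_within_zip": n_members,
            "n_total_files": n_files + n_members,
        }
        manifest.table1[repo] = row
        for k in ("n_datasets", "n_files", "n_zip_files", "n_files_within_zip", "n_total_files"):
            total[k] += row[k]
        total["total_size_gb"] += row["total_size_gb"]
        all_dates.extend(dates)
    if all_dates:
        total["first_dataset_date"] = min(all_dates)
        total["latest_dataset_date"] = max(all_dates)
    manifest.table1["total"] = total

    # engine / extension distributions over all visible files of kept datasets
    for ds in kept:
        for f in _visible_files(ds):
            ext = _ext_of(f.name)
            engine = _ENGINE_TABLE.get(ext, "unknown")
            manifest.engine_counts[engine] = manifest.engine_counts.get(engine, 0) + 1
            if engine == "unknown":
                manifest.extension_counts_unknown[ext] = (
                    manifest.extension_counts_unknown.get(ext, 0) + 1
                )

    # composition groups over every catalogue-visible .gro
    for ds in kept:
        for f in _visible_files(ds):
            if f.gro_label is not None:
                manifest.composition_groups[f.gro_label] = (
                    manifest.composition_groups.get(f.gro_label, 0) + 1
                )
                manifest.n_gro_files += 1

    # .mdp-derived truths
    long_total = 0
    long_cg = 0
    for ds in kept:
        for f in _visible_files(ds):
            if f.mdp_truth is None:
                continue
            truth = f.mdp_truth
            manifest.n_mdp_files += 1
            if "invalid" not in (truth["tcoupl"], truth["pcoupl"]):
                pair = f"{truth['tcoupl']}|{truth['pcoupl']}"
                manifest.coupling_pairs[pair] = manifest.coupling_pairs.get(pair, 0) + 1
            if truth["ref_t"] is not None:
                left = str(int(math.floor(truth["ref_t"][0] / 10.0) * 10.0))
                manifest.temperature_histogram_10k[left] = (
                    manifest.temperature_histogram_10k.get(left, 0) + 1
                )
            time_ns = truth["dt"] * truth["nsteps"] / 1000.0
            production = truth["integrator"] in ("md", "sd") and time_ns > 1.0
            if not production:
                continue
            manifest.n_production_mdp += 1
            coarse = truth["dt"] >= _CG_CUTOFF_PS
            if 1.0 < time_ns <= 50.0:
                band = _BAND_LABELS[0]
            elif 50.0 < time_ns <= 1000.0:
                band = _BAND_LABELS[1]
            else:
                band = _BAND_LABELS[2]
            manifest.time_bands[band] = manifest.time_bands.get(band, 0) + 1
            if time_ns > 1000.0:
                long_total += 1
                long_cg += int(coarse)
    for band in _BAND_LABELS:
        manifest.time_bands.setdefault(band, 0)
    manifest.cg_share_above_1us = (long_cg / long_total) if long_total else None

    # trajectory truth for the one-file-per-dataset sample: the
    # lexicographically first plain .xtc of each dataset that has any
    for ds in kept:
        candidates = sorted(
            (f.name, f) for f in ds.plain_files if f.xtc_truth is not None
        )
        if candidates:
            name, f = candidates[0]
            manifest.xtc_truth[f"{ds.repo}/{ds.dataset_id}/{name}"] = list(f.xtc_truth)
    return manifest


def gen_corpus(spec: CorpusSpec, out_dir: str | Path) -> Manifest:
    """Write a complete fixture tree + manifest; returns the manifest.

    The tree replays through :class:`~mdscout.transport.FixtureTransport`;
    ``manifest.json`` is written beside it.
    """
    spec.validate()
    config = spec.query_config or QueryConfig.default()
    queries = build_queries(config)
    rng = random.Random(spec.seed)
    out = Path(out_dir)
    writer = FixtureWriter(out)

    datasets: list[_PlantedDataset] = []
    for repo in ("zenodo", "figshare", "osf"):
        n_total = spec.n_datasets.get(repo, 0)
        n_decoys = spec.n_decoys.get(repo, 0)
        for i in range(n_total):
            is_decoy = i >= n_total - n_decoys
            datasets.append(_plant_dataset(rng, repo, i, is_decoy, spec.zip_member_factor))

    # materialize zip archives from their members
    for ds in datasets:
        for archive in ds.plain_files:
            if _ext_of(archive.name) == "zip":
                members = [m for m in ds.member_files if m.in_zip == archive.name]
                archive.content = _build_zip(members)

    # downloadable payloads + per-dataset record fixtures + previews
    from .repo_clients import CLIENTS

    for ds in datasets:
        urls = {
            f.name: writer.add_file(f"{ds.repo}/{ds.dataset_id}/{f.name}", f.content)
            for f in ds.plain_files
        }
        client = CLIENTS[ds.repo]
        writer.record(ds.repo, "record", client.record_params(ds.dataset_id), _record_payload(ds, urls))
        if ds.repo != "osf":
            for archive in ds.plain_files:
                if _ext_of(archive.name) == "zip":
                    members = [m for m in ds.member_files if m.in_zip == archive.name]
                    writer.record(
                        ds.repo,
                        "preview",
                        client.preview_params(ds.dataset_id, archive.name),
                        _preview_html(ds.repo, members),
                        kind="html",
                    )

    # search pages for every (repository, query) pair
    for repo in ("zenodo", "figshare", "osf"):
        repo_datasets = [d for d in datasets if d.repo == repo]
        for query in queries:
            hits = [d.dataset_id for d in repo_datasets if _query_hits(d, query)]
            _write_search_pages(writer, repo, query, hits)

    writer.flush()
    manifest = _enumerate_manifest(datasets, queries, config.target_extensions())
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
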