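"""Summary statistics over an index snapshot and its derived annotations.

Everything the harvest reports is computed here: per-repository dataset and
file counts, engine/extension distributions, empirical CDFs of system sizes
and simulation times, composition-group (upset) counts, thermostat–barostat
flow counts, the temperature histogram, and the one-file-per-dataset
trajectory sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .inference import CompositionProfile, MdpAnnotation, assign_engine
from .records import FileRecord, IndexSnapshot

#: Simulation-time report bands in ns: (1, 50], (50, 1000], (1000, inf).
TIME_BANDS_NS = ((1.0, 50.0), (50.0, 1000.0), (1000.0, math.inf))

GB = 1e9  # decimal gigabyte, as repository UIs report sizes


# -- Table-1-style repository summary ---------------------------------------


def repository_summary(index: IndexSnapshot) -> pd.DataFrame:
    """Per-repository dataset/file statistics plus a totals row.

    Columns: n_datasets, first_dataset_date, latest_dataset_date, n_files
    (plain), total_size_gb, n_zip_files, n_files_within_zip, n_total_files.
    """
    rows = []
    datasets = index.datasets
    for repo in sorted(datasets["repository"].unique()) if not datasets.empty else []:
        sub = datasets[datasets["repository"] == repo]
        dates = sorted(d for d in sub["publication_date"] if d)
        rows.append(
            {
                "repository": repo,
                "n_datasets": len(sub),
                "first_dataset_date": dates[0] if dates else "",
                "latest_dataset_date": dates[-1] if dates else "",
                "n_files": int(sub["n_files"].sum()),
                "total_size_gb": float(sub["total_size_bytes"].sum()) / GB,
                "n_zip_files": int(sub["n_zip_files"].sum()),
                "n_files_within_zip": int(sub["n_files_within_zip"].sum()),
            }
        )
    for row in rows:
        row["n_total_files"] = row["n_files"] + row["n_files_within_zip"]
    all_dates = sorted(d for r in rows for d in (r["first_dataset_date"], r["latest_dataset_date"]) if d)
    total = {
        "repository": "total",
        "n_datasets": sum(r["n_datasets"] for r in rows),
        "first_dataset_date": all_dates[0] if all_dates else "",
        "latest_dataset_date": all_dates[-1] if all_dates else "",
        "n_files": sum(r["n_files"] for r in rows),
        "total_size_gb": sum(r["total_size_gb"] for r in rows),
        "n_zip_files": sum(r["n_zip_files"] for r in rows),
        "n_files_within_zip": sum(r["n_files_within_zip"] for r in rows),
        "n_total_files": sum(r["n_total_files"] for r in rows),
    }
    rows.append(total)
    return pd.DataFrame(rows)


# -- distributions ----------------------------------------------------------


def engine_distribution(index: IndexSnapshot, include_zip_members: bool = True) -> dict[str, int]:
    """File count per MD engine; every file (plain + zip member) counted once."""
    files = index.files if include_zip_members else index.files[~index.files["from_zip"]]
    counts: dict[str, int] = {}
    for ext in files["file_extension"]:
        engine = assign_engine(ext)
        counts[engine] = counts.get(engine, 0) + 1
    return counts


def extension_top_k(
    index: IndexSnapshot, k: int, engine_filter: str | None = "unknown", include_zip_members: bool = True
) -> list[tuple[str, int]]:
    """k most observed extensions (descending count, ties alphabetical)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    files = index.files if include_zip_members else index.files[~index.files["from_zip"]]
    counts: dict[str, int] = {}
    for ext in files["file_extension"]:
        if engine_filter is not None and assign_engine(ext) != engine_filter:
            continue
        counts[ext] = counts.get(ext, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


@dataclass
class Ecdf:
    """Empirical CDF: fraction at x = (# values ≤ x) / n."""

    values: list[float] = field(default_factory=list)
    fractions: list[float] = field(default_factory=list)


def ecdf(values: list[float]) -> Ecdf:
    if not values:
        return Ecdf()
    ordered = sorted(values)
    n = len(ordered)
    fractions = []
    for i, v in enumerate(ordered):
        # step height at a tied value is the fraction ≤ that value
        j = i
        while j + 1 < n and ordered[j + 1] == v:
            j += 1
        fractions.append((j + 1) / n)
    return Ecdf(values=ordered, fractions=fractions)


def upset_counts(profiles: list[CompositionProfile]) -> dict[str, int]:
    """Systems per composition group label."""
    counts: dict[str, int] = {}
    for p in profiles:
        label = p.group_label
        counts[label] = counts.get(label, 0) + 1
    return counts


# -- .mdp flow / time / temperature analytics -------------------------------


def coupling_flows(
    annotations: list[MdpAnnotation], include_invalid: bool = False
) -> dict[tuple[str, str], int]:
    """(thermostat, barostat) pair counts.

    'invalid' values (outside the documented Gromacs options) are excluded
    by default; (none, none) pairs are genuine — they are the
    no-temperature-no-pressure-coupling class.
    """
    counts: dict[tuple[str, str], int] = {}
    for ann in annotations:
        if not include_invalid and ("invalid" in (ann.thermostat, ann.barostat)):
            continue
        pair = (ann.thermostat, ann.barostat)
        counts[pair] = counts.get(pair, 0) + 1
    return counts


@dataclass
class TimeDistribution:
    by_resolution: dict[str, Ecdf]
    band_counts: dict[str, int]
    cg_share_above_1us: float | None


def _band_label(lo: float, hi: float) -> str:
    return f"({lo:g}, {hi:g}] ns" if math.isfinite(hi) else f"> {lo:g} ns"


def time_distribution(annotations: list[MdpAnnotation]) -> TimeDistribution:
    """Simulation-time CDFs per resolution + band counts over production runs.

    Only production candidates enter. Band edges: (1, 50] ns, (50 ns, 1 µs],
    above 1 µs; the coarse-grain share of the top band is reported as a
    fraction in [0, 1].
    """
    production = [a for a in annotations if a.is_production_candidate and a.simulation_time_ns is not None]
    by_resolution = {
        res: ecdf([a.simulation_time_ns for a in production if a.resolution == res])
        for res in ("all-atom", "coarse-grain")
    }
    band_counts: dict[str, int] = {}
    for lo, hi in TIME_BANDS_NS:
        label = _band_label(lo, hi)
        band_counts[label] = sum(1 for a in production if lo < a.simulation_time_ns <= hi)
    top_lo = TIME_BANDS_NS[-1][0]
    top = [a for a in production if a.simulation_time_ns > top_lo]
    cg_share = None
    if top:
        cg_share = sum(1 for a in top if a.resolution == "coarse-grain") / len(top)
    return TimeDistribution(by_resolution=by_resolution, band_counts=band_counts, cg_share_above_1us=cg_share)


def temperature_histogram(
    annotations: list[MdpAnnotation], bin_width_k: float
) -> list[tuple[float, int]]:
    """(bin left edge, count) pairs over headline temperatures.

    Bins are left-closed right-open, aligned at multiples of the width;
    files without a temperature are excluded.
    """
    if bin_width_k <= 0:
        raise ValueError("bin_width_k must be > 0")
    counts: dict[float, int] = {}
    for ann in annotations:
        if ann.temperature_k is None:
            continue
        left = math.floor(ann.temperature_k / bin_width_k) * bin_width_k
        counts[left] = counts.get(left, 0) + 1
    return sorted(counts.items())


# -- trajectory sampling ----------------------------------------------------


def sample_one_per_dataset(index: IndexSnapshot, extension: str) -> list[FileRecord]:
    """One representative file of the given extension per dataset holding any.

    Plain (non-zip) files win over zip members; ties resolve to the
    lexicographically first path.
    """
    ext = extension.lower().lstrip(".")
    files = index.files[index.files["file_extension"] == ext]
    chosen: list[FileRecord] = []
    for (_repo, _did), group in files.groupby(["repository", "dataset_id"], sort=True):
        plain = group[~group["from_zip"]].sort_values("file_name")
        pick = plain.iloc[0] if not plain.empty else group[group["from_zip"]].sort_values("file_name").iloc[0]
        chosen.append(
            FileRecord(
                repository=pick["repository"],
                dataset_id=pick["dataset_id"],
                file_name=pick["file_name"],
                size_bytes=int(pick["size_bytes"]),
                from_zip=bool(pick["from_zip"]),
                origin_zip=pick["origin_zip"] or None,
                download_url=pick["download_url"] or None,
                file_extension=pick["file_extension"],
            )
        )
    return chosen
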