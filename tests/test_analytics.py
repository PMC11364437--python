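"""Summary statistics: small constructed examples plus manifest parity."""

from __future__ import annotations

import pytest

from mdscout import analytics
from mdscout.inference import CompositionProfile, MdpAnnotation
from mdscout.records import DatasetRecord, FileRecord, IndexSnapshot, datasets_frame, files_frame


def _index(datasets, files):
    return IndexSnapshot(
        datasets=datasets_frame(datasets), files=files_frame(files), harvest_date="2023-01-01"
    )


def _ds(repo, did, date="2021-01-01", **kw):
    defaults = dict(doi="", title="", description="", publication_date=date)
    defaults.update(kw)
    return DatasetRecord(repository=repo, dataset_id=did, **defaults)


def _ann(time_ns=None, resolution="unknown", thermo="none", baro="none", temp=None, production=False):
    return MdpAnnotation(
        simulation_time_ns=time_ns,
        resolution=resolution,
        thermostat=thermo,
        barostat=baro,
        temperature_k=temp,
        is_production_candidate=production,
    )


def test_repository_summary_totals_row():
    index = _index(
        [
            _ds("zenodo", "A", "2015-03-01", n_files=2, total_size_bytes=3_000_000_000,
                n_zip_files=1, n_files_within_zip=5),
            _ds("zenodo", "B", "2020-01-01", n_files=1, total_size_bytes=1_000_000_000),
            _ds("osf", "C", "2018-06-15", n_files=3, total_size_bytes=500_000_000),
        ],
        [],
    )
    summary = analytics.repository_summary(index)
    zenodo = summary[summary["repository"] == "zenodo"].iloc[0]
    assert zenodo["n_datasets"] == 2
    assert zenodo["first_dataset_date"] == "2015-03-01"
    assert zenodo["total_size_gb"] == pytest.approx(4.0)
    assert zenodo["n_total_files"] == 3 + 5
    total = summary[summary["repository"] == "total"].iloc[0]
    assert total["n_datasets"] == 3
    assert total["n_files"] == 6
    assert total["first_dataset_date"] == "2015-03-01"
    assert total["latest_dataset_date"] == "2020-01-01"
    # totals row equals element-wise sum of repository rows
    repo_rows = summary[summary["repository"] != "total"]
    for col in ("n_datasets", "n_files", "n_zip_files", "n_files_within_zip", "n_total_files"):
        assert total[col] == repo_rows[col].sum()


def test_repository_summary_empty_index():
    summary = analytics.repository_summary(_index([], []))
    assert list(summary["repository"]) == ["total"]
    assert summary.iloc[0]["n_datasets"] == 0
    assert summary.iloc[0]["first_dataset_date"] == ""


def test_engine_distribution_counts_every_file_once():
    index = _index(
        [_ds("zenodo", "A")],
        [
            FileRecord("zenodo", "A", "a.gro", 1),
            FileRecord("zenodo", "A", "b.pdb", 1),
            FileRecord("zenodo", "A", "in/c.mdp", 1, from_zip=True, origin_zip="z.zip"),
        ],
    )
    assert analytics.engine_distribution(index) == {"gromacs": 2, "unknown": 1}
    assert analytics.engine_distribution(index, include_zip_members=False) == {
        "gromacs": 1,
        "unknown": 1,
    }


def test_extension_top_k_order_and_ties():
    files = (
        [FileRecord("zenodo", "A", f"f{i}.dat", 1) for i in range(5)]
        + [FileRecord("zenodo", "A", f"g{i}.txt", 1) for i in range(3)]
        + [FileRecord("zenodo", "A", f"noext{i}", 1) for i in range(2)]
        + [FileRecord("zenodo", "A", "tie.aaa", 1), FileRecord("zenodo", "A", "tie.bbb", 1)]
    )
    index = _index([_ds("zenodo", "A")], files)
    top = analytics.extension_top_k(index, k=3)
    assert top == [("dat", 5), ("txt", 3), ("none", 2)]
    # ties break alphabetically, k beyond distinct extensions returns all
    full = analytics.extension_top_k(index, k=10)
    assert full[-2:] == [("aaa", 1), ("bbb", 1)]
    with pytest.raises(ValueError):
        analytics.extension_top_k(index, k=0)


def test_ecdf_definition_and_permutation_invariance():
    e = analytics.ecdf([1, 2, 2, 4])
    assert e.values == [1, 2, 2, 4]
    assert e.fractions == [0.25, 0.75, 0.75, 1.0]
    assert analytics.ecdf([4, 2, 1, 2]) == e
    assert analytics.ecdf([7.0]).fractions == [1.0]
    assert analytics.ecdf([]).values == []


def _profile(**counts):
    profile = CompositionProfile()
    profile.counts.update(counts)
    return profile


def test_upset_counts():
    profiles = [
        _profile(protein=5, lipid=3),
        _profile(protein=5, lipid=3, water_ions=100),
        _profile(protein=2),
        _profile(water_ions=30),
    ]
    assert analytics.upset_counts(profiles) == {
        "lipid+protein": 2,
        "protein": 1,
        "water/ions only": 1,
    }


def test_coupling_flows_excludes_invalid_by_default():
    annotations = [
        _ann(thermo="v-rescale", baro="parrinello-rahman"),
        _ann(thermo="v-rescale", baro="parrinello-rahman"),
        _ann(thermo="none", baro="none"),
        _ann(thermo="invalid", baro="berendsen"),
    ]
    flows = analytics.coupling_flows(annotations)
    assert flows == {
        ("v-rescale", "parrinello-rahman"): 2,
        ("none", "none"): 1,
    }
    with_invalid = analytics.coupling_flows(annotations, include_invalid=True)
    assert sum(with_invalid.values()) == 4


def test_time_distribution_bands_and_cg_share():
    annotations = [
        _ann(time_ns=10, resolution="all-atom", production=True),
        _ann(time_ns=100, resolution="all-atom", production=True),
        _ann(time_ns=2000, resolution="coarse-grain", production=True),
        _ann(time_ns=5000, resolution="coarse-grain", production=True),
        _ann(time_ns=1500, resolution="all-atom", production=True),
        _ann(time_ns=3000, resolution="coarse-grain", production=False),  # filtered out
    ]
    td = analytics.time_distribution(annotations)
    assert td.band_counts == {"(1, 50] ns": 1, "(50, 1000] ns": 1, "> 1000 ns": 3}
    assert td.cg_share_above_1us == pytest.approx(2 / 3)
    assert td.by_resolution["all-atom"].values == [10, 100, 1500]


def test_time_distribution_all_atomistic():
    td = analytics.time_distribution([_ann(time_ns=2000, resolution="all-atom", production=True)])
    assert td.cg_share_above_1us == 0.0


def test_temperature_histogram_binning():
    annotations = [_ann(temp=t) for t in (298, 300, 310, 400)] + [_ann(temp=None)]
    hist = analytics.temperature_histogram(annotations, bin_width_k=50)
    assert hist == [(250.0, 1), (300.0, 2), (400.0, 1)]
    assert analytics.temperature_histogram([], 50) == []
    with pytest.raises(ValueError):
        analytics.temperature_histogram(annotations, 0)


def test_sample_one_per_dataset_prefers_first_plain_file():
    index = _index(
        [_ds("zenodo", "A"), _ds("zenodo", "B"), _ds("zenodo", "C")],
        [
            FileRecord("zenodo", "A", "traj2.xtc", 1),
            FileRecord("zenodo", "A", "traj1.xtc", 1),
            FileRecord("zenodo", "B", "z/inner.xtc", 1, from_zip=True, origin_zip="z.zip"),
            FileRecord("zenodo", "C", "no_xtc.gro", 1),
        ],
    )
    sample = analytics.sample_one_per_dataset(index, "xtc")
    assert [(s.dataset_id, s.file_name) for s in sample] == [("A", "traj1.xtc"), ("B", "z/inner.xtc")]


def test_full_loop_matches_manifest_on_session_corpus(harvested):
    """Every analytics result equals the generator's brute-force manifest."""
    from conftest import summarize

    snapshot, manifest, content = harvested
    got = summarize(snapshot, content)
    assert got["kept"] == manifest.kept
    assert got["engine_counts"] == manifest.engine_counts
    assert got["composition_groups"] == manifest.composition_groups
    assert got["coupling_pairs"] == manifest.coupling_pairs
    assert got["time_bands"] == manifest.time_bands
    assert got["cg_share_above_1us"] == manifest.cg_share_above_1us
    assert got["temperature_histogram_10k"] == manifest.temperature_histogram_10k
    top = analytics.extension_top_k(snapshot, k=10)
    for ext, count in top:
        assert manifest.extension_counts_unknown[ext] == count
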