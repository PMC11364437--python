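"""Shared fixtures: one synthetic corpus harvested end to end."""

from __future__ import annotations

import pytest

from mdscout import analytics
from mdscout.fixtures import CorpusSpec, gen_corpus
from mdscout.repo_clients import QueryConfig
from mdscout.transport import FixtureTransport
from mdscout.workflows import annotate_gromacs_content, run_harvest

ALL_REPOS = ["zenodo", "figshare", "osf"]


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Seed-1 corpus: (root path, manifest)."""
    root = tmp_path_factory.mktemp("corpus")
    manifest = gen_corpus(CorpusSpec(seed=1), root)
    return root, manifest


@pytest.fixture(scope="session")
def corpus_transport(corpus):
    root, _ = corpus
    return FixtureTransport(root)


@pytest.fixture(scope="session")
def harvested(corpus, corpus_transport, tmp_path_factory):
    """(snapshot, manifest, gromacs content) after the full pipeline."""
    _, manifest = corpus
    snapshot = run_harvest(ALL_REPOS, QueryConfig.default(), corpus_transport, harvest_date="2023-03-01")
    cache = tmp_path_factory.mktemp("cache")
    content = annotate_gromacs_content(snapshot, corpus_transport, cache)
    return snapshot, manifest, content


def run_full_loop(seed: int, tmp_path):
    """Generate corpus `seed`, harvest it, parse its Gromacs files."""
    root = tmp_path / f"corpus{seed}"
    manifest = gen_corpus(CorpusSpec(seed=seed), root)
    transport = FixtureTransport(root)
    snapshot = run_harvest(ALL_REPOS, QueryConfig.default(), transport, harvest_date="2023-03-01")
    content = annotate_gromacs_content(snapshot, transport, tmp_path / f"cache{seed}")
    return manifest, snapshot, content


def summarize(snapshot, content):
    """All analytics results in manifest-comparable form."""
    flows = analytics.coupling_flows(content.annotations)
    td = analytics.time_distribution(content.annotations)
    return {
        "kept": sorted(
            f"{r}/{d}" for r, d in snapshot.datasets[["repository", "dataset_id"]].itertuples(index=False)
        ),
        "engine_counts": analytics.engine_distribution(snapshot),
        "composition_groups": analytics.upset_counts(content.profiles),
        "coupling_pairs": {f"{t}|{b}": n for (t, b), n in flows.items()},
        "time_bands": td.band_counts,
        "cg_share_above_1us": td.cg_share_above_1us,
        "temperature_histogram_10k": {
            str(int(left)): n for left, n in analytics.temperature_histogram(content.annotations, 10)
        },
    }
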