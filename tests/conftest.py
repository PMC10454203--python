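"""Shared fixtures: the default synthetic genome pair and its pipeline stages.

Everything heavy is session-scoped and computed once; individual tests
inspect different aspects of the same run.
"""

import pytest

from syntloss.loss import FilterThresholds, detect_losses, map_reads
from syntloss.orthology import reciprocal_best_hits
from syntloss.simulate import Event, SimConfig, simulate_pair, simulate_reads
from syntloss.synteny import chain_anchors, rank_anchors


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def genome_pair(default_config):
    return simulate_pair(default_config)


@pytest.fixture(scope="session")
def truth_events(genome_pair):
    _, _, truth = genome_pair
    return {t.gene_id: t.event for t in truth}


@pytest.fixture(scope="session")
def planted_events(truth_events):
    return {g: e for g, e in truth_events.items() if e is not Event.NONE}


@pytest.fixture(scope="session")
def fixture_anchors(genome_pair):
    ref, query, _ = genome_pair
    return reciprocal_best_hits(ref.proteins(), query.proteins())


@pytest.fixture(scope="session")
def fixture_blocks(genome_pair, fixture_anchors):
    ref, query, _ = genome_pair
    return chain_anchors(rank_anchors(fixture_anchors, ref, query))


@pytest.fixture(scope="session")
def fixture_reads(genome_pair, default_config):
    _, query, _ = genome_pair
    cfg = default_config
    return simulate_reads(
        query.sequences,
        coverage=cfg.read_coverage,
        read_len=cfg.read_len,
        error_rate=cfg.read_error_rate,
        seed=cfg.seed + 1,
    )


@pytest.fixture(scope="session")
def fixture_depth(genome_pair, fixture_reads):
    ref, _, _ = genome_pair
    track, stats = map_reads(fixture_reads, ref.anchored_sequences())
    return track


@pytest.fixture(scope="session")
def fixture_calls(genome_pair, fixture_blocks, fixture_depth):
    ref, query, _ = genome_pair
    return detect_losses(ref, query, fixture_blocks, fixture_depth, FilterThresholds())
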