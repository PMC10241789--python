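"""Shared fixtures: one synthetic study (seed 1) reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import crestreg.simulate as sim
from crestreg import linking, se_calling as sc


@pytest.fixture(scope="session")
def config() -> sim.SimulationConfig:
    return sim.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def genome(config):
    genes, fragments = sim.simulate_annotation(config)
    return genes, fragments


@pytest.fixture(scope="session")
def h3k27ac(config, genome):
    genes, _ = genome
    peaks, totals, truth = sim.simulate_h3k27ac(config, genes)
    counts = sim.peak_count_frame(peaks, list(config.populations))
    cpm = sc.compute_cpm(counts, totals)
    for peak, raw_row, cpm_row in zip(peaks, counts.values, cpm.values):
        peak.raw_counts, peak.cpm = raw_row, cpm_row
    return peaks, counts, totals, truth


@pytest.fixture(scope="session")
def se_results(config, genome, h3k27ac):
    genes, _ = genome
    peaks, _, _, _ = h3k27ac
    kept = sc.filter_peaks(peaks, genes, [], set(config.chromosomes()))
    regions = sc.stitch_peaks(kept, annotation=genes)
    return {
        pop: sc.call_superenhancers(regions, i, pop)
        for i, pop in enumerate(config.populations)
    }


@pytest.fixture(scope="session")
def interaction_tables(config, genome, h3k27ac):
    genes, fragments = genome
    _, _, _, truth = h3k27ac
    return sim.simulate_interactions(config, genes, fragments, truth)


@pytest.fixture(scope="session")
def expression(config, genome, h3k27ac):
    genes, _ = genome
    _, _, _, truth = h3k27ac
    return sim.simulate_expression(config, genes, truth)


@pytest.fixture(scope="session")
def se_links(se_results, interaction_tables, expression):
    return linking.link_ses_to_promoters(se_results, interaction_tables, expression)


@pytest.fixture(scope="session")
def accessibility(config):
    return sim.simulate_accessibility(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
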