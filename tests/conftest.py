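"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from crestmir.annotate import annotate_genome
from crestmir.mapping import GenomeIndex, map_exact
from crestmir.preprocess import collapse, trim_library
from crestmir.simulate import (SimConfig, generate_genome, precursor_queries,
                               simulate_library)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, depth_per_library=20_000)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome + truth + one library per tissue (replicates 1)."""
    genome, truth = generate_genome(small_config)
    libs = {
        tissue: simulate_library(truth, tissue, 1, small_config)
        for tissue in small_config.tissues
    }
    return genome, truth, libs


@pytest.fixture(scope="session")
def small_collapsed(small_study, small_config):
    _genome, _truth, libs = small_study
    counters, tallies = {}, {}
    for tissue, lib in libs.items():
        counters[lib.library], tallies[lib.library] = trim_library(
            (s for _n, s, _q in lib.reads), )
    return collapse(counters, tallies)


@pytest.fixture(scope="session")
def small_index(small_study):
    genome, _truth, _libs = small_study
    return GenomeIndex(genome)


@pytest.fixture(scope="session")
def small_mapping(small_collapsed, small_index):
    return map_exact(small_collapsed, small_index)


@pytest.fixture(scope="session")
def small_annotation(small_study, small_config):
    genome, truth, _libs = small_study
    queries = precursor_queries(truth, small_config)
    hairpins, audit = annotate_genome(genome, queries)
    return hairpins, audit


@pytest.fixture(scope="session")
def matched_totals(small_collapsed, small_mapping):
    matched = np.array([bool(small_mapping.get(s))
                        for s in small_collapsed.sequences])
    return pd.Series(small_collapsed.counts[matched].sum(axis=0),
                     index=small_collapsed.libraries)


@pytest.fixture(scope="session")
def tissue_map(small_study):
    _g, _t, libs = small_study
    return {lib.library: tissue for tissue, lib in libs.items()}
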