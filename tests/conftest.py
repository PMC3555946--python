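import numpy as np
import pandas as pd
import pytest

import isletmir as im


@pytest.fixture(scope="session")
def small_config():
    return im.SimulationConfig(
        seed=11, n_hairpins=10, reads_per_library=3000, n_libraries=2
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return im.make_reference(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_config, small_reference):
    abundances = {hp.id: w for hp, w in zip(
        small_reference.hairpins,
        np.exp(np.random.default_rng(5).standard_normal(10)),
    )}
    return im.simulate_reads(small_reference, abundances, small_config)


@pytest.fixture(scope="session")
def panel_sim():
    return im.simulate_tissue_panel(im.SimulationConfig(seed=21))


@pytest.fixture(scope="session")
def gwas_sim():
    return im.simulate_gwas(im.SimulationConfig(seed=31))


@pytest.fixture(scope="session")
def merged_scores(panel_sim):
    """Specificity scores on the default panel, after the full chain."""
    factors = im.inflation_factors(panel_sim.counts)
    linear = im.normalized_linear(panel_sim.counts, factors)
    panel = im.filter_min_expression(
        im.average_by_tissue(linear, panel_sim.library_tissues)
    )
    corr = im.profile_correlation(panel)
    profile_set = im.merge_similar_profiles(corr, panel)
    return profile_set, im.specificity_scores(profile_set)
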