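"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pytest

from pgebv.simulate import (SimConfig, GeneticMapSpec, default_map,
                            simulate_dh_genotypes, apply_gbs_noise,
                            assign_qtl_effects, simulate_study)


@pytest.fixture(scope="session")
def mini_config():
    """Desk-scale study: full line count, reduced markers/bands."""
    return SimConfig(n_snps=800, n_bands=16, n_flights=2, seed=11)


@pytest.fixture(scope="session")
def mini_study(mini_config):
    """(clean, noisy, truth, plots) for the desk-scale default study."""
    return simulate_study(mini_config)


@pytest.fixture(scope="session")
def mini_blues(mini_study):
    from pgebv.phenostats import build_blue_table
    _, _, _, plots = mini_study
    return build_blue_table(plots)


@pytest.fixture(scope="session")
def mini_binmap(mini_study):
    from pgebv.binmap import build_binmap
    _, noisy, _, _ = mini_study
    binmap, report = build_binmap(noisy)
    return binmap


@pytest.fixture(scope="session")
def clean_geno():
    """Noise-free DH genotypes, 97 lines x 1000 SNPs on 10 chromosomes."""
    spec = default_map(n_snps=1000)
    return simulate_dh_genotypes(spec, 97, seed=5)


@pytest.fixture()
def two_snp_map():
    return GeneticMapSpec([("c1", 20.0)], {"c1": np.array([0.0, 20.0])})
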