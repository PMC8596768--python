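"""Shared fixtures: a fast toy study (small sizes) for unit-level pipelines.

The toy study keeps locus diversity moderate (theta = 4*N*mu*L = 20) so that
summary statistics are well defined on essentially every simulated locus
while single simulations stay in the millisecond range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lsd import (
    SelectionRegime,
    build_reference_table,
    default_migration_priors,
    fit_transform,
    two_deme_im_model,
)

TOY_N = 500
TOY_MU = 5e-6
TOY_L = 2000
TOY_POPS = ["deme1", "deme2"]


@pytest.fixture(scope="session")
def toy_model():
    return two_deme_im_model(n1=TOY_N, n2=TOY_N, mutation_rate=TOY_MU)


@pytest.fixture(scope="session")
def toy_sample_config():
    return {"deme1": 10, "deme2": 10}


@pytest.fixture(scope="session")
def toy_priors():
    return default_migration_priors()


@pytest.fixture(scope="session")
def toy_table(toy_model, toy_priors, toy_sample_config):
    rng = np.random.default_rng(20_240_101)
    return build_reference_table(
        toy_model, toy_priors, 4000, toy_sample_config, TOY_L, rng, sfs_bins=4,
        seed_label=20_240_101,
    )


@pytest.fixture(scope="session")
def toy_transform(toy_table):
    return fit_transform(toy_table, 8)


@pytest.fixture(scope="session")
def toy_regime():
    # toy onset: 400 generations, standing variation at 0.1
    return SelectionRegime(s1=0.5, s2=0.5, t_onset=400.0)


def toy_neutral_stats(toy_model, toy_sample_config, n_loci, seed, m=5.0, sfs_bins=4):
    from lsd import simulate_locus, stats_vector

    rng = np.random.default_rng(seed)
    params = {"M12": m, "M21": m}
    rows = [
        stats_vector(
            simulate_locus(toy_model, params, toy_sample_config, TOY_L, rng),
            TOY_POPS,
            sfs_bins=sfs_bins,
        )
        for _ in range(n_loci)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)
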