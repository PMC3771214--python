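"""Shared fixtures: the canonical small study and one full-model fit.

The canonical fixture is a desk-scale realistic study (4 subjects x 10
sessions x 4 categories x 5 dv levels x 30 choices per block) with fixed,
realistic ground truth.  The model-6 fit on it is session-scoped because
several diagnostics tests reuse the same posterior.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from socialvalue import (
    ChainConfig,
    ModelSpec,
    run_mcmc,
    simulate_dataset,
    small_study_design,
    small_study_truth,
)

#: fixed seeds for the canonical fixture and its fit (chosen once)
FIXTURE_DATA_SEED = 101
FIXTURE_CHAIN_SEED = 11

#: desk-scale chain protocol used for fixture fits throughout the suite
DESK_CHAINS = dict(n_chains=2, n_adapt=300, n_burn=600, n_iter=1600, thin=4)


@pytest.fixture(scope="session")
def canonical():
    design = small_study_design()
    truth = small_study_truth(design)
    dataset, realized = simulate_dataset(
        truth, design, np.random.default_rng(FIXTURE_DATA_SEED))
    return SimpleNamespace(design=design, truth=truth, realized=realized,
                           dataset=dataset)


@pytest.fixture(scope="session")
def fitted(canonical):
    config = ChainConfig(seed=FIXTURE_CHAIN_SEED, **DESK_CHAINS)
    return run_mcmc(ModelSpec.from_model_number(6), canonical.dataset, config)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A very small study for fast structural tests (72 blocks)."""
    design = small_study_design(N_per_block=15)
    design = type(design)(subjects=("A", "B"), session_counts=(3, 3),
                          dv_grid=(-0.04, 0.0, 0.04), N_per_block=15)
    truth = small_study_truth(design)
    dataset, _ = simulate_dataset(truth, design, np.random.default_rng(5))
    return SimpleNamespace(design=design, truth=truth, dataset=dataset)
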