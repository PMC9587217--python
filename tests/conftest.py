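"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from micromod.layout import make_layout
from micromod.synth import (
    generate_spikes,
    generate_var_lfp,
    modular_var_truth,
    module_tuning,
    plant_modules,
)


@pytest.fixture(scope="session")
def layout44():
    return make_layout(4, 4, 0.4)


@pytest.fixture(scope="session")
def planted2(layout44):
    return plant_modules(layout44, 2, seed=0)


@pytest.fixture(scope="session")
def var_truth(planted2, layout44):
    return modular_var_truth(planted2, layout44, order=4, seed=3)


@pytest.fixture(scope="session")
def var_blocks(planted2, var_truth):
    _, blocks, _ = generate_var_lfp(planted2, var_truth, n_blocks=10, block_len=2.5, seed=11)
    return blocks


@pytest.fixture(scope="session")
def tuned_spikes(planted2):
    tuning = module_tuning(planted2, gain=3.0, seed=1)
    spikes, trials = generate_spikes(planted2, tuning, n_trials=120, seed=2)
    return spikes, trials


@pytest.fixture(scope="session")
def white_blocks():
    """Independent-channel Gaussian blocks (no causal structure)."""
    from micromod.session import BlockSet

    rng = np.random.default_rng(42)
    blocks = [rng.standard_normal((6, 2000)) for _ in range(8)]
    return BlockSet(blocks=blocks, fs=1000.0)
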