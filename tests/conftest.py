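"""Shared fixtures: a small motif library, designs, and simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from motifcaller.design import OligoDesign, encode_blocks, random_library
from motifcaller.simulate import ErrorRates, SimConfig, build_pore_model, simulate_run


@pytest.fixture(scope="session")
def design():
    return OligoDesign()


@pytest.fixture(scope="session")
def library(design):
    return random_library(n=8, l=25, min_hamming=10, seed=1, design=design)


@pytest.fixture(scope="session")
def blocks(design, library):
    return encode_blocks(12, design, library, seed=2)


@pytest.fixture(scope="session")
def truths(blocks):
    return {b.block_id: b for b in blocks}


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free squiggle settings (constant dwell, no drops, no noise)."""
    return SimConfig(dwell_mean=8, dwell_dispersion=0.0, noise_sd=0.0, event_drop_prob=0.0)


@pytest.fixture(scope="session")
def clean_pore():
    return build_pore_model(K=6, seed=7, level_sd=0.0)


@pytest.fixture(scope="session")
def clean_run(blocks, library, design, clean_cfg, clean_pore):
    """Error-free run: exact squiggles and verbatim basecalls."""
    return simulate_run(
        blocks, library, design, coverage=4,
        cfg=clean_cfg, error_rates=ErrorRates(0.0, 0.0, 0.0), pore=clean_pore, seed=5,
    )


@pytest.fixture(scope="session")
def noisy_run(blocks, library, design):
    """Default regime: 2% substitutions, 2% insertions, 6% deletions."""
    return simulate_run(blocks, library, design, coverage=8, seed=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def study():
    """The scaled-down end-to-end study: simulate, search, label, train, score.

    Shared across the acceptance tests because the caller training dominates
    its cost; seed-pinned so every assertion sees the same run.
    """
    from motifcaller.pipeline import run_study

    return run_study(seed=1, log=lambda _msg: None)
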