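"""Shared fixtures: small synthetic instances reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import triadpart as tp

SEED = 0


@pytest.fixture(scope="session")
def small_triplets():
    """Five simulated triplets (1 kb, 2% divergence) with truth."""
    genes, truths = tp.simulate_triplets(5, 1000, 0.02, seed=SEED)
    return genes, truths


@pytest.fixture(scope="session")
def expressed_truths(small_triplets):
    """The same triplets with expression truth filled on a small design."""
    _, truths = small_triplets
    design = tp.SimDesign(depth=5000, error_rate=0.0, seed=SEED)
    tp.simulate_expression(truths, design, seed=SEED + 1)
    return truths, design


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
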