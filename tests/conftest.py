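"""Shared fixtures.

The enhancement-recovery experiment (training the contrast-removal network
over ten seeds) is by far the most expensive computation in the suite, so
it runs once per session and its results are shared by every test that
needs a trained model or its training history.
"""

from __future__ import annotations

import numpy as np
import pytest

from vncct.experiments import enhancement_recovery

RECOVERY_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def recovery_results():
    """Ten independent enhancement-recovery runs (one per seed)."""
    return [enhancement_recovery(seed) for seed in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
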