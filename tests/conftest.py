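"""Shared fixtures.

The full-tissue simulations (14 x 20 = 280 cells, 30 simulated minutes)
are the expensive part of the suite, so they are session-scoped and
shared between the invariant, phenotype and pipeline tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from germband.simulate import simulate_gbe
from germband.tracks import ScriptedT1, generate_scripted_t1_lattice

BATCH_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def sdk_run_checked():
    """One full sdk run with per-step invariant monitoring enabled."""
    return simulate_gbe("sdk", seed=1, check_invariants=True)


@pytest.fixture(scope="session")
def wt_batch():
    """Five WT runs at fixed seeds (invariants checked on the first)."""
    return [
        simulate_gbe("WT", seed=s, check_invariants=(s == BATCH_SEEDS[0]))
        for s in BATCH_SEEDS
    ]


@pytest.fixture(scope="session")
def sdk_batch(sdk_run_checked):
    """Five sdk runs at the same seeds as the WT batch."""
    return [sdk_run_checked] + [
        simulate_gbe("sdk", seed=s, check_invariants=False) for s in BATCH_SEEDS[1:]
    ]


@pytest.fixture(scope="session")
def ideal_t1_tracks():
    """An idealised T1 among regular hexagons: the shrinking junction is
    vertical (DV-oriented), the gaining pair sits directly above and
    below, and frames are 30 s apart."""
    script = ScriptedT1(
        losing=(12, 13), shrink_start=5, swap_frame=25, hold_frames=0, regrow_frames=20
    )
    return generate_scripted_t1_lattice([script], n_frames=61, rows=5, cols=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
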