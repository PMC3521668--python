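"""Shared fixtures.

The expensive simulation campaigns are session-scoped so the spike-shape,
spikelet-range and trend tests all reuse one set of runs.
"""

import numpy as np
import pytest

from iosim.network import build_grid
from iosim.simulate import integrate, settle, single_cell_network


@pytest.fixture(scope="session")
def single_cell_run():
    """Default isolated cell: 1 s settle (discarded) + 5 s recording."""
    net = single_cell_network()
    y0 = settle(net, settle_ms=1000.0)
    return integrate(net, duration=5000.0, y0=y0)


@pytest.fixture(scope="session")
def phase_sweep_07():
    """Evoked-AP campaign at default g_CaL: center-cell 5.5 pA / 20 ms pulses
    in a homogeneous 3×3 network, 100 onsets 2 ms apart (one per trial)."""
    from iosim.protocols import run_gcal_sweep

    return run_gcal_sweep(g_values=(0.7,), n_trials=100, onset_step_ms=2.0)


@pytest.fixture(scope="session")
def lowg_sweep():
    """Same protocol at g_CaL = 0.55 mS/cm² (40 onsets, 5 ms apart)."""
    from iosim.protocols import run_gcal_sweep

    return run_gcal_sweep(g_values=(0.55,), n_trials=40, onset_step_ms=5.0)


@pytest.fixture(scope="session")
def full_network_sweep():
    """Full-network stimulation counterpart of the phase sweep (reduced n)."""
    from iosim.protocols import run_phase_dependency

    return run_phase_dependency(n_trials=60, onset_step_ms=3.0,
                                conditions=("intrinsic/full",))


@pytest.fixture(scope="session")
def ensemble_200():
    """Ensemble-synchrony campaign, 3×3 heterogeneous networks, 200 trials."""
    from iosim.protocols import run_ensemble_synchrony

    return run_ensemble_synchrony((3, 3), n_trials=200, root_seed=2024)


@pytest.fixture(scope="session")
def sync_50():
    """Unstimulated synchronization runs, 3×3 heterogeneous, 50 seeds."""
    from iosim.protocols import run_synchronization

    return run_synchronization((3, 3), n_seeds=50, root_seed=2024)


@pytest.fixture(scope="session")
def settled_3x3():
    net = build_grid(3, 3)
    return net, settle(net, settle_ms=1500.0)
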