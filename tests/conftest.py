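"""Shared fixtures: session-scoped shear ensembles sized for a desk run.

The ensembles are the expensive part of the suite (minutes, not
seconds), so they are built once per session and shared between the
unit tests and the acceptance tests.  All randomness is fixed by
explicit seeds; nothing here reads the wall clock or the filesystem.
"""

from dataclasses import replace

import numpy as np
import pytest

from voroshear import (EnergyParams, ProtocolConfig, fd_shear_modulus,
                       random_state, relax, run_shear)

SOLID_P0 = 3.72
N_CELLS = 64

# p0 grid and seed count of the startup-rigidity scan
G0_P0_GRID = (3.74, 3.76, 3.78, 3.80, 3.82, 3.84, 3.86, 3.88)
G0_SEEDS = range(8)

# p0 values and seeds of the yield-transition ensemble; the deep-fluid
# conditions (p0 >= 4) flow at machine-zero stress from the first steps,
# so their strain ramps are kept short to stay inside the time budget
TRANSITION_SPEC = {3.90: (0, 1), 3.95: (0,), 4.00: (0,), 4.05: (0,)}
TRANSITION_GAMMA = {3.90: (0.5, 0.25), 3.95: (0.5, 0.25),
                    4.00: (0.3, 0.15), 4.05: (0.3, 0.15)}


def _run(p0: float, seed: int, gamma_max: float,
         steady_gamma_min: float) -> "Trajectory":
    cfg = ProtocolConfig(gamma_max=gamma_max,
                         steady_gamma_min=steady_gamma_min,
                         g_every=1, seed=seed)
    state = random_state(N_CELLS, seed=seed)
    return run_shear(state, EnergyParams(p0=p0), cfg)


@pytest.fixture(scope="session")
def solid_trajs():
    """Four seeds of the deep-solid condition (p0=3.72), gamma up to 0.7.

    Used for stress inference, avalanche statistics, the correlation
    field and the SGR noise-temperature calibration.
    """
    return [_run(SOLID_P0, seed, gamma_max=0.7, steady_gamma_min=0.35)
            for seed in range(4)]


@pytest.fixture(scope="session")
def transition_trajs():
    """Trajectories across the yield transition, keyed by p0."""
    return {p0: [_run(p0, seed, gamma_max=TRANSITION_GAMMA[p0][0],
                      steady_gamma_min=TRANSITION_GAMMA[p0][1])
                 for seed in seeds]
            for p0, seeds in TRANSITION_SPEC.items()}


@pytest.fixture(scope="session")
def g0_scan():
    """Startup (gamma=0) shear moduli on a p0 grid, 8 seeds each.

    Returns ``(p0_grid, moduli)`` with ``moduli[i, s]`` the modulus of
    seed ``s`` relaxed at ``p0_grid[i]`` and zero strain.
    """
    grid = np.array(G0_P0_GRID)
    moduli = np.empty((len(grid), len(list(G0_SEEDS))))
    for i, p0 in enumerate(grid):
        params = EnergyParams(p0=float(p0))
        for s in G0_SEEDS:
            st = relax(random_state(N_CELLS, seed=s), params)
            moduli[i, s] = fd_shear_modulus(st, params)
    return grid, moduli


@pytest.fixture(scope="session")
def relaxed_solid_states():
    """A few minimized solid states for modulus cross-checks."""
    out = []
    for p0, seed in [(3.70, 0), (3.70, 1), (3.72, 2), (3.75, 3)]:
        params = EnergyParams(p0=p0)
        out.append((relax(random_state(N_CELLS, seed=seed), params), params))
    return out
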