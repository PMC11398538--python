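import numpy as np
import pytest

from voroshear import (EnergyParams, FixtureSpec, MinimizationError,
                       ProtocolConfig, energy, fd_shear_modulus,
                       fire_minimize, honeycomb_state, make_fixture,
                       noise_floor_crossing, random_state, relax, run_shear,
                       stress_vanishing_point, tessellate, yield_stress)
from voroshear.fixtures import HEX_SHAPE_INDEX


def test_honeycomb_is_force_balanced():
    state = honeycomb_state(64)
    params = EnergyParams(p0=3.65)
    relaxed, log = fire_minimize(state, params)
    assert log.converged
    assert log.iterations == 0                # already at a minimum
    assert np.allclose(relaxed.positions, state.positions, atol=1e-12)


def test_perturbed_honeycomb_returns_to_lattice_energy():
    params = EnergyParams(p0=3.65)
    e_hex = 64 * (HEX_SHAPE_INDEX - 3.65) ** 2
    state = make_fixture(FixtureSpec("perturbed_honeycomb", 64, seed=1,
                                     noise=1e-3))
    relaxed = relax(state, params)
    assert np.isclose(energy(tessellate(relaxed), params), e_hex, rtol=1e-9)


def test_relax_solid_reaches_force_tolerance():
    params = EnergyParams(p0=3.70)
    relaxed, log = fire_minimize(random_state(64, seed=0), params,
                                 prerelax=True)
    assert log.converged
    assert log.residual <= 1e-14
    assert fd_shear_modulus(relaxed, params) > 1e-3


def test_relax_fluid_converges_on_energy_floor():
    # above the transition the minimum sits on the zero-energy manifold:
    # the residual is roundoff there and the energy floor certifies it
    params = EnergyParams(p0=4.2)
    relaxed, log = fire_minimize(random_state(64, seed=0), params,
                                 prerelax=True)
    assert log.converged
    assert log.energy_final < 1e-22
    assert fd_shear_modulus(relaxed, params) == 0.0


def test_minimization_error_carries_state():
    cfg = ProtocolConfig(max_iter=3, polish=False)
    with pytest.raises(MinimizationError) as exc:
        fire_minimize(random_state(64, seed=1), EnergyParams(p0=3.7), cfg)
    assert exc.value.state is not None


def test_run_shear_bookkeeping_and_elastic_branch():
    params = EnergyParams(p0=3.72)
    cfg = ProtocolConfig(gamma_max=0.02, steady_gamma_min=0.01, g_every=1,
                         seed=0)
    traj = run_shear(random_state(64, seed=0), params, cfg)
    assert len(traj.frames) == 11
    assert np.allclose(traj.gammas, 2e-3 * np.arange(11), atol=1e-12)
    assert all(f.residual <= 1e-12 for f in traj.frames)
    # elastic branch: no rearrangements, stress grows with slope ~ G
    if not traj.t1_events:
        dsig = np.diff(traj.sigmas) / np.diff(traj.gammas)
        g = np.array([f.shear_modulus for f in traj.frames])
        assert np.all(dsig > 0)
        assert np.allclose(dsig, 0.5 * (g[:-1] + g[1:]), rtol=0.1)
    # yield_stress averages the steady window
    ys = yield_stress(traj)
    mask = traj.gammas >= 0.01
    assert np.isclose(ys, traj.sigmas[mask].mean())


def test_protocol_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig(dgamma=-0.1)
    with pytest.raises(ValueError):
        ProtocolConfig(force_tol=0.0)
    with pytest.raises(ValueError):
        ProtocolConfig(gamma_max=0.5, steady_gamma_min=0.5)


def test_noise_floor_crossing_helper():
    p0 = [3.7, 3.8, 3.9, 4.0]
    assert np.isclose(noise_floor_crossing(p0, [1e-2, 1e-3, 0.0, 0.0]), 3.85)
    with pytest.raises(ValueError):
        noise_floor_crossing(p0, [1e-2, 1e-3, 1e-4, 1e-5])   # never crosses
    with pytest.raises(ValueError):
        noise_floor_crossing(p0, [1e-2, 0.0, 1e-3, 0.0])     # non-monotone


def test_stress_vanishing_point_helper():
    p0 = [3.9, 3.95, 4.0, 4.05]
    assert stress_vanishing_point(p0, [2e-3, 5e-4, 1e-6, 0.0]) == 4.0
    with pytest.raises(ValueError):
        stress_vanishing_point(p0, [2e-3, 1e-3, 5e-4, 3e-4])
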