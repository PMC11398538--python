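import numpy as np
import pytest

from voroshear import (EnergyParams, NotMinimizedError, affine_energy_slope,
                       apply_affine_shear, edge_tension, energy,
                       energy_and_forces, finite_difference_modulus, forces,
                       honeycomb_state, random_state, relax, shear_modulus,
                       shear_stress, tessellate)
from voroshear.fixtures import HEX_SHAPE_INDEX


def test_honeycomb_energy_closed_form():
    state = honeycomb_state(64)
    for p0 in (3.65, HEX_SHAPE_INDEX, 3.9):
        e = energy(tessellate(state), EnergyParams(p0=p0))
        assert np.isclose(e, 64 * (HEX_SHAPE_INDEX - p0) ** 2, atol=1e-10)


def test_honeycomb_tension_and_stress():
    mesh = tessellate(honeycomb_state(64))
    params = EnergyParams(p0=3.65)
    T = edge_tension(mesh, params)
    assert np.allclose(T, 4.0 * (HEX_SHAPE_INDEX - 3.65), atol=1e-9)
    # unsheared symmetric lattice carries no shear stress
    assert abs(shear_stress(mesh, params)) < 1e-9


def test_forces_match_finite_differences():
    # 20 random states, including strained boxes and an area-elastic case
    h = 1e-6
    for case in range(20):
        rng = np.random.default_rng(100 + case)
        state = random_state(32, seed=100 + case)
        if case % 3 == 0:
            state = apply_affine_shear(state, rng.uniform(-0.2, 0.2))
        params = EnergyParams(p0=3.6 + 0.05 * case,
                              kappa_A=1.0 if case % 4 == 0 else 0.0)
        F = forces(state, params)

        def energy_at(pos):
            st = type(state)(pos, state.box, state.gamma)
            return energy(tessellate(st), params)

        fd = np.empty_like(F)
        for i in range(state.n):
            for d in range(2):
                pp = state.positions.copy()
                pp[i, d] += h
                pm = state.positions.copy()
                pm[i, d] -= h
                fd[i, d] = -(energy_at(pp) - energy_at(pm)) / (2 * h)
        scale = np.abs(F).max()
        assert scale > 0
        assert np.abs(F - fd).max() / scale < 1e-6


def test_net_force_vanishes():
    for seed in range(3):
        state = random_state(64, seed=seed)
        F = forces(state, EnergyParams(p0=3.8))
        assert np.abs(F.sum(axis=0)).max() < 1e-10 * np.abs(F).max()


def test_stress_equals_affine_energy_slope():
    # per-configuration identity: virial stress == affine vertex-motion
    # energy slope, minimized or not
    cases = [(random_state(64, seed=7), EnergyParams(p0=3.8)),
             (apply_affine_shear(random_state(64, seed=8), 0.15),
              EnergyParams(p0=3.72))]
    for state, params in cases:
        mesh = tessellate(state)
        sig = shear_stress(mesh, params)
        slope = affine_energy_slope(mesh, params)
        assert abs(sig - slope) / max(abs(sig), 1e-12) < 1e-6


def test_shear_modulus_matches_fd_oracle(relaxed_solid_states):
    for state, params in relaxed_solid_states:
        g_lr = shear_modulus(state, params)
        g_fd = finite_difference_modulus(
            state, params, lambda s: relax(s, params))
        assert g_fd > 1e-3            # genuinely solid
        assert abs(g_lr - g_fd) / g_fd < 1e-5


def test_shear_modulus_requires_minimized_state():
    state = random_state(64, seed=11)
    with pytest.raises(NotMinimizedError):
        shear_modulus(state, EnergyParams(p0=3.7))


def test_energy_and_forces_consistent():
    state = random_state(32, seed=12)
    params = EnergyParams(p0=3.85)
    e, F = energy_and_forces(state, params)
    assert np.isclose(e, energy(tessellate(state), params), rtol=1e-12)
    assert np.allclose(F, forces(state, params), atol=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        EnergyParams(p0=3.8, kappa_A=-1.0)
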