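import numpy as np
import pytest

from voroshear import (DegenerateTissueError, EnergyParams, TissueState,
                       apply_affine_shear, edge_ensemble, energy,
                       honeycomb_state, minimum_image, random_state,
                       tessellate, wrap_positions)
from voroshear.fixtures import HEX_SHAPE_INDEX


def test_honeycomb_is_regular_hexagons():
    mesh = tessellate(honeycomb_state(64))
    assert np.allclose(mesh.areas, 1.0, atol=1e-9)
    assert np.allclose(mesh.perimeters, HEX_SHAPE_INDEX, atol=1e-9)
    # all edges equal length, each cell has six neighbors
    assert np.ptp(mesh.edge_length) < 1e-9
    assert all(len(v) == 6 for v in mesh.neighbor_graph.values())


def test_euler_counts_on_torus():
    # trivalent tiling of the torus: V = 2N, E = 3N, F = N
    for state in (honeycomb_state(64), random_state(64, seed=3)):
        mesh = tessellate(state)
        assert mesh.n_edges == 3 * mesh.n
        assert mesh.n_physical_vertices() == 2 * mesh.n


def test_areas_tile_the_box():
    state = random_state(100, seed=1)
    mesh = tessellate(state)
    Lx, Ly = state.box
    assert np.isclose(mesh.areas.sum(), Lx * Ly, rtol=1e-12)
    assert np.all(mesh.areas > 0)


def test_translation_invariance():
    state = random_state(64, seed=2)
    m0 = tessellate(state)
    shifted = TissueState(state.positions + np.array([0.37, -1.21]),
                          state.box, state.gamma)
    m1 = tessellate(shifted)
    assert np.allclose(np.sort(m0.areas), np.sort(m1.areas), atol=1e-10)
    assert np.allclose(np.sort(m0.perimeters), np.sort(m1.perimeters),
                       atol=1e-10)


def test_wrap_positions_idempotent_and_in_box():
    rng = np.random.default_rng(0)
    box, gamma = (5.0, 4.0), 0.3
    pos = rng.uniform(-20, 20, size=(50, 2))
    w = wrap_positions(pos, box, gamma)
    assert np.all((w[:, 1] >= 0) & (w[:, 1] < box[1]))
    assert np.allclose(wrap_positions(w, box, gamma), w, atol=1e-12)


def test_minimum_image_reduction():
    box, gamma = (4.0, 4.0), 0.25
    Lx, Ly = box
    rng = np.random.default_rng(1)
    d = rng.uniform(-8, 8, size=(200, 2))
    m = minimum_image(d, box, gamma)
    # the result differs from the input by a Lees-Edwards lattice vector
    my = np.round((d[:, 1] - m[:, 1]) / Ly)
    mx = np.round((d[:, 0] - m[:, 0] - my * gamma * Ly) / Lx)
    assert np.allclose(d[:, 1] - m[:, 1], my * Ly, atol=1e-12)
    assert np.allclose(d[:, 0] - m[:, 0], mx * Lx + my * gamma * Ly,
                       atol=1e-12)
    # components are reduced into the primary cell
    assert np.all(np.abs(m[:, 1]) <= Ly / 2 + 1e-12)
    assert np.all(np.abs(m[:, 0]) <= Lx / 2 + 1e-12)
    # already-short displacements are untouched
    small = rng.uniform(-0.5, 0.5, size=(50, 2))
    assert np.allclose(minimum_image(small, box, gamma), small, atol=1e-12)


def test_lees_edwards_strain_periodicity():
    # for a square box, gamma and gamma + 1 describe the same tiling
    state = random_state(64, seed=4)
    state = TissueState(state.positions, state.box, gamma=0.3)
    shifted = TissueState(state.positions, state.box, gamma=1.3)
    params = EnergyParams(p0=3.8)
    e0 = energy(tessellate(state), params)
    e1 = energy(tessellate(shifted), params)
    assert np.isclose(e0, e1, rtol=1e-12)


def test_apply_affine_shear():
    state = random_state(16, seed=0)
    dg = 0.01
    sheared = apply_affine_shear(state, dg)
    assert np.isclose(sheared.gamma, state.gamma + dg)
    expect = state.positions.copy()
    expect[:, 0] += dg * expect[:, 1]
    expect = wrap_positions(expect, state.box, sheared.gamma)
    assert np.allclose(sheared.positions, expect, atol=1e-12)


def test_degenerate_generators_raise():
    pos = np.array([[1.0, 1.0], [1.0, 1.0], [3.0, 3.0], [1.0, 3.0]])
    with pytest.raises(DegenerateTissueError):
        tessellate(TissueState(pos, (4.0, 4.0), 0.0))


def test_edge_ensemble_normalization():
    mesh = tessellate(random_state(64, seed=5))
    ens = edge_ensemble(mesh)
    assert np.isclose(ens.l.mean(), 1.0, rtol=1e-12)
    assert np.all((ens.omega >= 0) & (ens.omega < 180))
    assert len(ens.l) == len(ens.omega)
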