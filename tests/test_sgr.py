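import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from voroshear import (SGRParams, closed_form_yield_stress,
                       invert_solid_fraction, predict_yield_curve,
                       solid_fraction_map, steady_state, trap_density)
from voroshear.sgr import trap_point_mass


def test_params_validation():
    with pytest.raises(ValueError):
        SGRParams(chi=-0.1)
    with pytest.raises(ValueError):
        SGRParams(chi=0.1, f0=1.5)
    with pytest.raises(ValueError):
        SGRParams(chi=0.1, k=0.0)


def test_trap_density_is_k_gamma():
    p = SGRParams(chi=0.05, f0=0.25, kappa_shape=2.0)
    E = np.linspace(0.0, 5.0, 50)
    # kappa = 2: rho(E) = (1 - f0) E exp(-E)
    assert np.allclose(trap_density(p, E), 0.75 * E * np.exp(-E))
    assert trap_point_mass(p) == 0.25
    total = quad(lambda e: trap_density(p, e), 0, np.inf)[0]
    assert np.isclose(total + trap_point_mass(p), 1.0, atol=1e-9)
    with pytest.raises(ValueError):
        trap_density(p, -1.0)


def test_closed_form_matches_gamma_functions():
    # sigma_y(chi -> 0) = sqrt(k/2) <E> / <sqrt(E)> over the k-gamma law
    for k, kappa in [(0.0386, 2.0), (0.1, 2.0), (0.0386, 1.0)]:
        p = SGRParams(chi=0.01, k=k, kappa_shape=kappa)
        expect = np.sqrt(k / 2.0) * kappa / (gamma_fn(kappa + 0.5)
                                             / gamma_fn(kappa))
        assert np.isclose(closed_form_yield_stress(p), expect, rtol=1e-12)


def test_steady_state_solution_properties():
    p = SGRParams(chi=0.05, f0=0.2)
    sol = steady_state(p, gamma_dot=1e-3)
    assert np.isclose(sol.normalization, 1.0, atol=1e-7)
    assert sol.sigma > 0 and sol.mean_l > 0
    assert 0.0 <= sol.rho_solid <= 1.0
    assert sol.yielding_rate > 0
    # survival decreases in l
    S = sol.survival(1.0, np.array([0.0, 0.5, 1.0]))
    assert S[0] == 1.0 and np.all(np.diff(S) < 0)


def test_sigma_monotone_in_chi_and_f0_at_fixed_rate():
    base = steady_state(SGRParams(chi=0.05, f0=0.0), 1e-3).sigma
    assert steady_state(SGRParams(chi=0.20, f0=0.0), 1e-3).sigma < base
    assert steady_state(SGRParams(chi=0.05, f0=0.5), 1e-3).sigma < base


def test_solid_fraction_inversion_round_trip():
    chi = 0.08
    for f0 in (0.0, 0.3, 0.9):
        rho = solid_fraction_map(chi, f0)
        assert 0.0 <= rho <= 1.0
        assert np.isclose(invert_solid_fraction(rho, chi), f0, atol=1e-10)
    assert invert_solid_fraction(1.0, chi) == 0.0
    assert invert_solid_fraction(0.0, chi) == 1.0
    with pytest.raises(ValueError):
        invert_solid_fraction(1.2, chi)


def test_predict_yield_curve_scales_with_solid_fraction():
    chi = np.full(3, 0.05)
    rho = np.array([1.0, 0.5, 0.0])
    sig = predict_yield_curve(np.array([3.85, 3.95, 4.05]), chi, rho,
                              rate_ladder=(1e-2, 1e-3, 1e-4))
    assert sig[0] > 0
    assert np.isclose(sig[1], 0.5 * sig[0], rtol=0.05)
    assert sig[2] < 1e-3 * sig[0]          # vanished (rate-limited residue)
    with pytest.raises(ValueError):
        predict_yield_curve(np.array([3.9]), chi, rho)
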