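"""Dual-state Soft Glassy Rheology model of tissue yield stress.

Mesoscopic elements sit in energy traps of depth E, strain elastically
(local strain l, stress k*l) as the tissue is sheared at rate gamma_dot,
and yield by activated hops at rate Gamma0 * exp[-(E - k l^2/2)/x], where
x is the mechanical noise temperature.  On yielding an element is reborn
at l = 0 in a new trap drawn from the dual-state density

    rho(E) = f0 * delta(E) + (1 - f0) * Gamma(kappa_shape, x0),

mixing zero-barrier (fluid) traps with k-gamma distributed (solid) traps.
The quasi-static yield stress is sigma = k <l> in the steady state,
extrapolated to gamma_dot -> 0.  The steady state is constructed by
characteristics: an element born in trap E survives to strain l with
probability

    S_E(l) = exp[ -(Gamma0/gamma_dot) e^{-E/x}
                  sqrt(pi x / (2 k)) erfi( l sqrt(k/(2x)) ) ],

and the stationary density is the birth-rate-weighted residence density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special


@dataclass(frozen=True)
class SGRParams:
    """Trap-model parameters.

    chi = x/x0 is the mechanical-noise ratio, f0 the zero-barrier trap
    probability, k the element elastic constant, kappa_shape the k-gamma
    shape, x0 the mean trap-energy scale (units of energy), Gamma0 the
    attempt rate (units of time).
    """

    chi: float
    f0: float = 0.0
    k: float = 0.0386
    kappa_shape: float = 2.0
    x0: float = 1.0
    Gamma0: float = 1.0

    def __post_init__(self):
        if self.chi <= 0:
            raise ValueError("chi must be positive")
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        if self.k <= 0 or self.kappa_shape <= 0 or self.x0 <= 0 \
                or self.Gamma0 <= 0:
            raise ValueError("k, kappa_shape, x0, Gamma0 must be positive")

    @property
    def x(self) -> float:
        return self.chi * self.x0


def trap_density(params: SGRParams, E) -> np.ndarray:
    """Continuous part of the dual-state trap density at energies ``E``.

    The full density is f0*delta(E) plus this Gamma(kappa_shape, x0) part
    scaled by (1 - f0); the delta contribution is not representable
    pointwise and is accounted for by ``trap_point_mass``.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("trap energies must be non-negative")
    kap, x0 = params.kappa_shape, params.x0
    dens = (E ** (kap - 1.0) * np.exp(-E / x0)
            / (special.gamma(kap) * x0 ** kap))
    return (1.0 - params.f0) * dens


def trap_point_mass(params: SGRParams) -> float:
    """Weight of the zero-barrier delta component."""
    return params.f0


def _log_erfi(z: np.ndarray) -> np.ndarray:
    """log(erfi(z)) for z >= 0, stable for large arguments."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, -np.inf)
    small = (z > 0) & (z < 25.0)
    big = z >= 25.0
    out[small] = np.log(special.erfi(z[small]))
    zb = z[big]
    # erfi(z) ~ e^{z^2}/(z sqrt(pi)) (1 + 1/(2 z^2) + 3/(4 z^4))
    out[big] = (zb ** 2 - np.log(zb * math.sqrt(math.pi))
                + np.log1p(0.5 / zb ** 2 + 0.75 / zb ** 4))
    return out


@dataclass
class SGRSolution:
    """Stationary state at one shear rate.

    The density over (E, l) is P(E, l) = (Gamma/gamma_dot) rho(E) S_E(l)
    with the zero-barrier component carried separately; ``tau0``/``tau1``
    are the zeroth/first l-moments of the survival function per trap depth.
    """

    params: SGRParams
    gamma_dot: float
    e_nodes: np.ndarray        # continuous-part trap depths (quadrature)
    e_weights: np.ndarray      # probability weights summing to 1 - f0
    tau0: np.ndarray           # int S_E(l) dl at e_nodes
    tau1: np.ndarray           # int l S_E(l) dl at e_nodes
    tau0_zero: float           # same moments for the E = 0 traps
    tau1_zero: float
    sigma: float               # k <l>
    mean_l: float
    rho_solid: float           # residence-weighted fraction with E > 0
    yielding_rate: float       # Gamma = gamma_dot / <tau_l>

    def survival(self, E: float, l) -> np.ndarray:
        return _survival(self.params, self.gamma_dot, E, np.asarray(l, float))

    def density(self, E: float, l) -> np.ndarray:
        """Continuous-part density value P(E, l)."""
        rhoE = trap_density(self.params, E)
        return (self.yielding_rate / self.gamma_dot) * rhoE \
            * self.survival(E, l)

    @property
    def normalization(self) -> float:
        """Integral of the stationary density (should be 1)."""
        p = self.params
        w_tau = float(self.e_weights @ self.tau0) + p.f0 * self.tau0_zero
        return (self.yielding_rate / self.gamma_dot) * w_tau


def _survival(params: SGRParams, gamma_dot: float, E: float,
              l: np.ndarray) -> np.ndarray:
    x, k = params.x, params.k
    a = math.sqrt(k / (2.0 * x))
    c1 = (math.log(params.Gamma0 / gamma_dot)
          + 0.5 * math.log(math.pi * x / (2.0 * k)))
    log_a_hazard = c1 + _log_erfi(a * np.asarray(l, float)) - E / x
    return np.exp(-np.exp(np.minimum(log_a_hazard, 700.0)))


def _survival_moments(params: SGRParams, gamma_dot: float,
                      E: float) -> tuple[float, float]:
    """(int S dl, int l S dl) for one trap depth, adaptive quadrature."""
    x, k = params.x, params.k
    a = math.sqrt(k / (2.0 * x))
    c1 = (math.log(params.Gamma0 / gamma_dot)
          + 0.5 * math.log(math.pi * x / (2.0 * k)))

    def log_hazard(l):
        return c1 + float(_log_erfi(np.array([a * l]))[0]) - E / x

    # locate the yield front (log hazard = 0) and a hard cutoff where the
    # survival is numerically zero (log hazard = 6, S < 1e-175)
    def bracket(target):
        lo, hi = 1e-300, 1.0
        while log_hazard(hi) < target:
            hi *= 2.0
            if hi > 1e12:
                return hi
        if log_hazard(lo) >= target:
            return lo
        return optimize.brentq(lambda l: log_hazard(l) - target, lo, hi,
                               xtol=1e-15, rtol=1e-12)

    l_front = bracket(0.0)
    l_max = bracket(6.0)

    def S(l):
        return float(_survival(params, gamma_dot, E, np.array([l]))[0])

    pts = [p for p in (l_front,) if 0.0 < p < l_max]
    tau0 = integrate.quad(S, 0.0, l_max, points=pts, limit=200,
                          epsabs=1e-12, epsrel=1e-9)[0]
    tau1 = integrate.quad(lambda l: l * S(l), 0.0, l_max, points=pts,
                          limit=200, epsabs=1e-12, epsrel=1e-9)[0]
    return tau0, tau1


def _energy_quadrature(params: SGRParams, n_nodes: int):
    """Probability-weighted nodes for the Gamma(kappa, x0) trap mixture.

    Gauss-Laguerre nodes against weight e^{-t} give
    E[f(E)] = sum_i w_i t_i^{kappa-1} / Gamma(kappa) * f(x0 t_i)
    for E ~ Gamma(kappa, x0); weights are scaled by (1 - f0).
    """
    t, w = np.polynomial.laguerre.laggauss(n_nodes)
    kap = params.kappa_shape
    pw = w * t ** (kap - 1.0) / special.gamma(kap)
    pw = pw / pw.sum()          # remove residual quadrature error
    return params.x0 * t, (1.0 - params.f0) * pw


def steady_state(params: SGRParams, gamma_dot: float,
                 n_energy: int = 60) -> SGRSolution:
    """Stationary element distribution at shear rate ``gamma_dot``.

    Built along characteristics: the birth rate Gamma follows from
    normalization, Gamma/gamma_dot = 1 / <tau0> with tau0(E) the mean
    strain to yield; the stress is sigma = k <l> with
    <l> = <tau1> / <tau0> residence-weighted over the trap mixture.
    """
    if gamma_dot <= 0:
        raise ValueError("gamma_dot must be positive")
    e_nodes, e_weights = _energy_quadrature(params, n_energy)
    tau0 = np.empty(n_energy)
    tau1 = np.empty(n_energy)
    for i, E in enumerate(e_nodes):
        tau0[i], tau1[i] = _survival_moments(params, gamma_dot, float(E))
    tau0_zero, tau1_zero = _survival_moments(params, gamma_dot, 0.0)
    denom = float(e_weights @ tau0) + params.f0 * tau0_zero
    numer = float(e_weights @ tau1) + params.f0 * tau1_zero
    if not np.isfinite(denom) or denom <= 0:
        raise RuntimeError(
            f"steady state failed: residence normalization {denom!r} at "
            f"gamma_dot={gamma_dot:g}, chi={params.chi:g}, f0={params.f0:g}")
    mean_l = numer / denom
    rho_solid = float(e_weights @ tau0) / denom
    return SGRSolution(
        params=params, gamma_dot=gamma_dot, e_nodes=e_nodes,
        e_weights=e_weights, tau0=tau0, tau1=tau1, tau0_zero=tau0_zero,
        tau1_zero=tau1_zero, sigma=params.k * mean_l, mean_l=mean_l,
        rho_solid=rho_solid, yielding_rate=gamma_dot / denom)


DEFAULT_RATE_LADDER = tuple(10.0 ** -e for e in range(2, 7))


def quasistatic_yield_stress(params: SGRParams,
                             rate_ladder=DEFAULT_RATE_LADDER,
                             n_energy: int = 60,
                             monotone_tol: float = 1e-10) -> float:
    """sigma_yield = lim_{gamma_dot -> 0} sigma(gamma_dot).

    Evaluates the stationary stress down a decreasing geometric ladder of
    gamma_dot / Gamma0 and returns the value at the smallest rate; the
    ladder must be monotone (up to ``monotone_tol``) or an error is
    raised with the offending values.
    """
    rates = sorted(rate_ladder, reverse=True)
    sig = [steady_state(params, g, n_energy).sigma for g in rates]
    diffs = np.diff(sig)
    if not (np.all(diffs >= -monotone_tol) or np.all(diffs <= monotone_tol)):
        raise RuntimeError(
            "non-monotone stress ladder (numerical failure): "
            + ", ".join(f"sigma({g:g})={s:.6g}" for g, s in zip(rates, sig)))
    return float(sig[-1])


def closed_form_yield_stress(params: SGRParams) -> float:
    """chi -> 0, f0 = 0 limit: sigma_yield = sqrt(k/2) <E> / <sqrt(E)>.

    Without noise every element yields deterministically at
    l_y = sqrt(2 E / k); residence-weighting over strain gives
    <l> = <l_y^2/2> / <l_y>.  For E ~ Gamma(kappa, x0):
    <E> = kappa x0 and <sqrt(E)> = sqrt(x0) Gamma(kappa+1/2)/Gamma(kappa).
    """
    kap, x0 = params.kappa_shape, params.x0
    meanE = kap * x0
    mean_sqrtE = math.sqrt(x0) * special.gamma(kap + 0.5) / special.gamma(kap)
    return math.sqrt(params.k / 2.0) * meanE / mean_sqrtE


# --------------------------------------------------------------------------
# calibration from simulation
# --------------------------------------------------------------------------

REFERENCE_RATE = 1e-4      # gamma_dot/Gamma0 at which rho_solid(f0) is read


def solid_fraction_map(chi: float, f0: float, k: float = 0.0386,
                       kappa_shape: float = 2.0,
                       gamma_dot: float = REFERENCE_RATE) -> float:
    """Model rho_solid at small finite rate, as a function of f0."""
    p = SGRParams(chi=chi, f0=f0, k=k, kappa_shape=kappa_shape)
    return steady_state(p, gamma_dot).rho_solid


def invert_solid_fraction(rho_solid: float, chi: float, k: float = 0.0386,
                          kappa_shape: float = 2.0,
                          gamma_dot: float = REFERENCE_RATE) -> float:
    """f0 such that the model's residence-weighted solid fraction equals
    the measured ``rho_solid``.

    The map has the closed form rho = (1-f0) A / (f0 B + (1-f0) A) with
    A = <tau0>_Gamma and B = tau0(E=0), both independent of f0, so the
    inversion is exact: f0 = A (1-rho) / (rho B + A (1-rho)).
    """
    if not 0.0 <= rho_solid <= 1.0:
        raise ValueError(f"rho_solid={rho_solid!r} outside the attainable "
                         "range [0, 1] of the solid-fraction map")
    p = SGRParams(chi=chi, f0=0.0, k=k, kappa_shape=kappa_shape)
    e_nodes, e_weights = _energy_quadrature(p, 60)
    A = float(e_weights @ [_survival_moments(p, gamma_dot, float(E))[0]
                           for E in e_nodes])
    B = _survival_moments(p, gamma_dot, 0.0)[0]
    if rho_solid == 0.0:
        return 1.0
    return A * (1.0 - rho_solid) / (rho_solid * B + A * (1.0 - rho_solid))


@dataclass
class Calibration:
    """Per-condition SGR inputs measured from simulation."""

    chi: float
    f0: float
    mean_drop: float       # <Delta E>: per-cell energy dissipated per T1
    mean_energy: float     # <E>: per-cell energy over solid frames
    rho_solid: float


def calibrate_from_simulation(trajectories, g_threshold: float = 1e-8,
                              c: float = 1.0, k: float = 0.0386,
                              kappa_shape: float = 2.0,
                              gamma_dot: float = REFERENCE_RATE,
                              steady_gamma_min: float | None = None
                              ) -> Calibration:
    """Measure (chi, f0) for one condition from a trajectory ensemble.

    chi = c * <Delta E> / <E>: <Delta E> is the average per-cell energy
    dissipated per rearrangement during yielding steps (per-cell energy
    drop of each yielding strain step divided by its T1 count) and <E> the average
    per-cell energy over solid frames (G > g_threshold) in the steady
    regime.  f0 comes from inverting the model's solid-fraction map at
    the measured rho_solid.  ``c`` is the proportionality constant of the
    noise relation (default 1).
    """
    from .shear import solid_fraction

    drops, n_t1 = 0.0, 0
    solid_energies = []
    rhos = []
    for traj in trajectories:
        mask = traj.steady_mask(steady_gamma_min)
        idx = np.flatnonzero(mask)
        energies = traj.energies
        n = traj.frames[0].state.n
        events_by_step: dict[int, int] = {}
        for ev in traj.t1_events:
            events_by_step[ev.strain_index] = \
                events_by_step.get(ev.strain_index, 0) + 1
        for i in idx:
            fr = traj.frames[int(i)]
            if traj.modulus_at(int(i)) > g_threshold:
                solid_energies.append(energies[int(i)] / n)
            k_step = fr.index
            if k_step >= 1 and events_by_step.get(k_step, 0) > 0:
                # per-cell energy drop, same units as the solid energies
                de = (energies[k_step - 1] - energies[k_step]) / n
                if de > 0:
                    drops += de
                    n_t1 += events_by_step[k_step]
        rhos.append(solid_fraction(traj, g_threshold=g_threshold,
                                   steady_gamma_min=steady_gamma_min))
    if n_t1 == 0 or not solid_energies:
        raise ValueError("trajectories carry no yielding events in the "
                         "solid state; cannot calibrate chi")
    mean_drop = drops / n_t1
    mean_energy = float(np.mean(solid_energies))
    chi = c * mean_drop / mean_energy
    rho = float(np.mean(rhos))
    f0 = invert_solid_fraction(rho, chi, k=k, kappa_shape=kappa_shape,
                               gamma_dot=gamma_dot)
    return Calibration(chi=chi, f0=f0, mean_drop=mean_drop,
                       mean_energy=mean_energy, rho_solid=rho)


def predict_yield_curve(p0_grid, chi, rho_solid, k: float = 0.0386,
                        kappa_shape: float = 2.0,
                        rate_ladder=DEFAULT_RATE_LADDER,
                        gamma_dot: float = REFERENCE_RATE) -> np.ndarray:
    """SGR yield stress on a p0 grid from measured chi(p0), rho_solid(p0).

    For each grid point, f0 is obtained by inverting the solid-fraction
    map and sigma_yield from the quasi-static ladder; the curve vanishes
    where the calibration drives the model out of the glassy regime
    (f0 -> 1 or chi >= 1).

    The solid-fraction constraint is re-imposed at every rung of the
    rate ladder (f0 slaved to the measured rho_solid at that rate): the
    zero-barrier residence vanishes with gamma_dot, so holding f0 fixed
    while gamma_dot -> 0 would degenerate to the pure-solid stress for
    any f0 < 1.  With the constraint the limit is regular,
    sigma_yield -> rho_solid * sigma_solid(chi).
    """
    p0_grid = np.asarray(p0_grid, float)
    chi = np.asarray(chi, float)
    rho_solid = np.asarray(rho_solid, float)
    if not (len(p0_grid) == len(chi) == len(rho_solid)):
        raise ValueError("p0_grid, chi and rho_solid must align")
    rates = sorted(rate_ladder, reverse=True)
    out = np.empty(len(p0_grid))
    for i in range(len(p0_grid)):
        sig = []
        for g in rates:
            f0 = invert_solid_fraction(float(rho_solid[i]), float(chi[i]),
                                       k=k, kappa_shape=kappa_shape,
                                       gamma_dot=g)
            params = SGRParams(chi=float(chi[i]), f0=f0, k=k,
                               kappa_shape=kappa_shape)
            sig.append(steady_state(params, g).sigma)
        out[i] = sig[-1]
    return out
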