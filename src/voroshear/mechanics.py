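"""Vertex-model mechanics: energy, forces, tensions, stress, shear modulus.

The tissue energy is the standard dimensionless shape functional

    eps = sum_i [ kappa_A (a_i - 1)^2 + (p_i - p0)^2 ]

with a_i, p_i the Voronoi cell areas and perimeters and p0 the preferred
cell shape index.  Forces on cell centers are the exact analytic gradient,
obtained by the chain rule through the Voronoi vertices: every vertex is
the circumcenter of a Delaunay triangle of three generators, and the
circumcenter Jacobians have closed rank-1 forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (TissueState, VoronoiMesh, _GeometryBundle,
                       _build_geometry, apply_affine_shear, tessellate)


@dataclass(frozen=True)
class EnergyParams:
    """Energy-functional parameters.

    kappa_A is the rescaled area elasticity (default 0, the pure-perimeter
    regime with unit perimeter modulus); p0 is the preferred shape index.
    """

    p0: float
    kappa_A: float = 0.0

    def __post_init__(self):
        if self.kappa_A < 0:
            raise ValueError("kappa_A must be non-negative")


@dataclass
class MechanicalObservables:
    """Per-frame mechanical state: energy, forces, stress, tensions."""

    energy: float
    forces: np.ndarray
    sigma_xy: float
    tensions: np.ndarray
    shear_modulus: float | None = None


# --------------------------------------------------------------------------
# energy / tension / stress on a mesh
# --------------------------------------------------------------------------

def cell_energies(mesh: VoronoiMesh, params: EnergyParams) -> np.ndarray:
    return (params.kappa_A * (mesh.areas - 1.0) ** 2
            + (mesh.perimeters - params.p0) ** 2)


def energy(mesh: VoronoiMesh, params: EnergyParams) -> float:
    """Total tissue energy eps >= 0 when kappa_A terms are included."""
    return float(cell_energies(mesh, params).sum())


def edge_tension(mesh: VoronoiMesh, params: EnergyParams) -> np.ndarray:
    """Scalar tension on each edge, T_ij = 2[(p_i - p0) + (p_j - p0)].

    The tension vector is T_ij * lhat_ij along the edge; only the scalar is
    returned here (the direction lives in mesh.edge_vec).  The formula is
    the perimeter-term derivative d eps / d l_ij and holds in the kappa_A
    regime used throughout (area terms do not couple to edge length).
    """
    dp = mesh.perimeters - params.p0
    return 2.0 * (dp[mesh.edge_i] + dp[mesh.edge_j])


def shear_stress(mesh: VoronoiMesh, params: EnergyParams) -> float:
    """Tissue shear stress sigma_xy = (1/N) sum_{i<j} T^x_ij l^y_ij.

    T^x is the x-component of the tension vector (scalar tension times the
    edge unit vector) and l^y the y-component of the edge vector.
    """
    T = edge_tension(mesh, params)
    L = mesh.edge_length
    keep = L > 1e-14
    lx = mesh.edge_vec[keep, 0]
    ly = mesh.edge_vec[keep, 1]
    return float(np.sum(T[keep] * lx * ly / L[keep]) / mesh.n)


# --------------------------------------------------------------------------
# analytic forces
# --------------------------------------------------------------------------

def _energy_forces_bundle(b: _GeometryBundle, params: EnergyParams):
    """Energy and minus-gradient from a prebuilt geometry bundle."""
    n = b.n
    kA, p0 = params.kappa_A, params.p0
    areas, perims = b.areas, b.perimeters
    eps = float(np.sum(kA * (areas - 1.0) ** 2 + (perims - p0) ** 2))

    v = b.circum[b.inc_simplex]
    vx, vy = v[:, 0], v[:, 1]
    nxt, prv, cell = b.nxt, b.prv, b.inc_cell

    # d area / d vertex  (shoelace)
    dax = 0.5 * (vy[nxt] - vy[prv])
    day = 0.5 * (vx[prv] - vx[nxt])
    # d perimeter / d vertex
    d1x, d1y = vx - vx[prv], vy - vy[prv]
    d2x, d2y = vx - vx[nxt], vy - vy[nxt]
    n1 = np.hypot(d1x, d1y)
    n2 = np.hypot(d2x, d2y)
    n1 = np.where(n1 > 1e-14, n1, np.inf)   # zero-length Voronoi edge guard
    n2 = np.where(n2 > 1e-14, n2, np.inf)
    dpx = d1x / n1 + d2x / n2
    dpy = d1y / n1 + d2y / n2

    ca = 2.0 * kA * (areas - 1.0)[cell]
    cp = 2.0 * (perims - p0)[cell]
    gx = ca * dax + cp * dpx
    gy = ca * day + cp * dpy

    m = b.simplices.shape[0]
    dEdCx = np.bincount(b.inc_simplex, weights=gx, minlength=m)
    dEdCy = np.bincount(b.inc_simplex, weights=gy, minlength=m)

    active = (dEdCx != 0.0) | (dEdCy != 0.0)
    simp = b.simplices[active]
    c = b.circum[active]
    g = np.column_stack([dEdCx[active], dEdCy[active]])

    q1 = b.points[simp[:, 0]]
    q2 = b.points[simp[:, 1]]
    q3 = b.points[simp[:, 2]]
    r2 = q2 - q1
    r3 = q3 - q1
    det = 4.0 * (r2[:, 0] * r3[:, 1] - r2[:, 1] * r3[:, 0])
    det = np.where(np.abs(det) > 1e-300, det, np.inf)
    # Minv rows of M = 2*[[r2],[r3]]:  Minv = (1/det) [[2*r3y, -2*r2y],
    #                                                  [-2*r3x, 2*r2x]]
    inv00 = 2.0 * r3[:, 1] / det
    inv01 = -2.0 * r2[:, 1] / det
    inv10 = -2.0 * r3[:, 0] / det
    inv11 = 2.0 * r2[:, 0] / det
    # u_a = 2 Minv [1,1]^T ; u_b = 2 Minv e1 ; u_c = 2 Minv e2
    uax = 2.0 * (inv00 + inv01)
    uay = 2.0 * (inv10 + inv11)
    ubx, uby = 2.0 * inv00, 2.0 * inv10
    ucx, ucy = 2.0 * inv01, 2.0 * inv11

    # gradient contribution of slot s: (u_s . g) * w_s, with
    # w_a = c - q1, w_b = q2 - c, w_c = q3 - c
    sa = uax * g[:, 0] + uay * g[:, 1]
    sb = ubx * g[:, 0] + uby * g[:, 1]
    sc = ucx * g[:, 0] + ucy * g[:, 1]
    wa = c - q1
    wb = q2 - c
    wc = q3 - c

    bases = b.base[simp]
    idx = bases.ravel()
    valx = np.column_stack([sa * wa[:, 0], sb * wb[:, 0], sc * wc[:, 0]]).ravel()
    valy = np.column_stack([sa * wa[:, 1], sb * wb[:, 1], sc * wc[:, 1]]).ravel()
    grad = np.column_stack([np.bincount(idx, weights=valx, minlength=n),
                            np.bincount(idx, weights=valy, minlength=n)])
    return eps, -grad


def forces(state: TissueState, params: EnergyParams,
           margin: float | None = None) -> np.ndarray:
    """Analytic forces -d eps / d r_i on the cell centers."""
    b = _build_geometry(state, margin=margin, check_degenerate=False,
                        with_edges=False)
    return _energy_forces_bundle(b, params)[1]


def energy_and_forces(state: TissueState, params: EnergyParams,
                      margin: float | None = None) -> tuple[float, np.ndarray]:
    b = _build_geometry(state, margin=margin, check_degenerate=False,
                        with_edges=False)
    return _energy_forces_bundle(b, params)


def observables(state: TissueState, params: EnergyParams,
                with_modulus: bool = False,
                g_kwargs: dict | None = None) -> MechanicalObservables:
    """Energy, forces, stress and tensions of a state in one pass."""
    b = _build_geometry(state)
    eps, F = _energy_forces_bundle(b, params)
    mesh = _mesh_from_bundle(b)
    obs = MechanicalObservables(
        energy=eps, forces=F, sigma_xy=shear_stress(mesh, params),
        tensions=edge_tension(mesh, params))
    if with_modulus:
        obs.shear_modulus = shear_modulus(state, params, **(g_kwargs or {}))
    return obs


def _mesh_from_bundle(b: _GeometryBundle) -> VoronoiMesh:
    return VoronoiMesh(
        n=b.n, box=b.box, gamma=b.gamma, areas=b.areas,
        perimeters=b.perimeters, edge_i=b.edge_i, edge_j=b.edge_j,
        edge_image=b.edge_image, edge_length=b.edge_length,
        edge_angle=b.edge_angle, edge_vec=b.edge_vec, edge_mid=b.edge_mid,
        _bundle=b)


# --------------------------------------------------------------------------
# shear modulus by nonaffine linear response
# --------------------------------------------------------------------------

class NotMinimizedError(RuntimeError):
    """Shear modulus requested on a state that is not force balanced."""


def _affine_probe(state: TissueState, params: EnergyParams, dg: float):
    s = apply_affine_shear(state, dg)
    return energy_and_forces(s, params)


def _forces_and_stress(state: TissueState, params: EnergyParams):
    b = _build_geometry(state, check_degenerate=False, with_edges=True)
    F = _energy_forces_bundle(b, params)[1]
    return F, shear_stress(_mesh_from_bundle(b), params)


def shear_modulus(state: TissueState, params: EnergyParams,
                  residual_tol: float = 1e-10, fd_step: float = 1e-5,
                  eig_cutoff: float = 1e-10, fast: bool = False) -> float:
    """Instantaneous shear modulus by nonaffine linear response.

    G = dsigma/dgamma along the minimized path,

        G = dsigma/dgamma|_r  -  (grad_r sigma) . H^+ Xi,

    where H is the Hessian of the energy with respect to cell centers,
    Xi = d2eps/dgamma dr is the affine force field, and H^+ a
    pseudo-inverse excluding the two zero translation modes (eigenvalues
    below ``eig_cutoff`` are dropped).  -H^+ Xi is the nonaffine
    displacement field per unit strain, so the second term is the stress
    relaxation carried by the nonaffine motion.

    Note that for a Voronoi tissue G differs from the curvature of the
    minimized energy, (1/N) d2eps/dgamma2|min: the stress is the junction
    virial, and Voronoi vertices (triangle circumcenters) do not move
    affinely with the cell centers, so sigma is not (1/N) deps/dgamma.
    The energy curvature is available as :func:`energy_shear_modulus`.

    All derivatives are assembled by differences of the analytic forces
    and the virial stress (central, or one-sided with ``fast=True`` for
    classification work); the state must be force balanced first.
    """
    F0, sig0 = _forces_and_stress(state, params)
    res = np.abs(F0).max()
    if res > residual_tol:
        raise NotMinimizedError(
            f"residual force {res:.2e} exceeds {residual_tol:.2e}; "
            "minimize the state before computing G")
    n = state.n
    dof = 2 * n
    h = fd_step

    H = np.empty((dof, dof))
    gsig = np.empty(dof)
    pos0 = state.positions
    for j in range(dof):
        dp = np.zeros_like(pos0)
        dp[j // 2, j % 2] = h
        Fp, sp = _forces_and_stress(
            TissueState(pos0 + dp, state.box, state.gamma,
                        seed=state.seed), params)
        if fast:
            H[:, j] = -(Fp - F0).ravel() / h
            gsig[j] = (sp - sig0) / h
        else:
            Fm, sm = _forces_and_stress(
                TissueState(pos0 - dp, state.box, state.gamma,
                            seed=state.seed), params)
            H[:, j] = -(Fp - Fm).ravel() / (2.0 * h)
            gsig[j] = (sp - sm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    return _modulus_from_parts(state, params, gsig, H, eig_cutoff, h)


def _modulus_from_parts(state, params, gsig, H, eig_cutoff, h):
    """dsigma/dgamma|_r + grad sigma . dr/dgamma with dr/dgamma = -H^+ Xi."""
    _, F_p = _affine_probe(state, params, +h)
    _, F_m = _affine_probe(state, params, -h)
    xi = -(F_p - F_m).ravel() / (2.0 * h)
    sp = _forces_and_stress(apply_affine_shear(state, +h), params)[1]
    sm = _forces_and_stress(apply_affine_shear(state, -h), params)[1]
    dsig_dgamma = (sp - sm) / (2.0 * h)
    evals, evecs = np.linalg.eigh(H)
    keep = evals > eig_cutoff
    dr = -(evecs[:, keep] @ ((evecs[:, keep].T @ xi) / evals[keep]))
    return float(dsig_dgamma + gsig @ dr)


def energy_shear_modulus(state: TissueState, params: EnergyParams,
                         fd_step: float = 1e-5,
                         eig_cutoff: float = 1e-10) -> float:
    """Curvature of the minimized energy, (1/N)[d2eps/dgamma2 - Xi^T H^+ Xi].

    This is the elastic constant of the energy landscape; it differs from
    the slope of the virial stress for a Voronoi tissue (see
    :func:`shear_modulus`).
    """
    n = state.n
    dof = 2 * n
    h = fd_step
    eps_p, F_p = _affine_probe(state, params, +h)
    eps_m, F_m = _affine_probe(state, params, -h)
    eps_0 = energy_and_forces(state, params)[0]
    d2e_dg2 = (eps_p - 2.0 * eps_0 + eps_m) / h ** 2
    xi = -(F_p - F_m).ravel() / (2.0 * h)
    H = np.empty((dof, dof))
    pos0 = state.positions
    for j in range(dof):
        dp = np.zeros_like(pos0)
        dp[j // 2, j % 2] = h
        Fp = forces(TissueState(pos0 + dp, state.box, state.gamma,
                                seed=state.seed), params)
        Fm = forces(TissueState(pos0 - dp, state.box, state.gamma,
                                seed=state.seed), params)
        H[:, j] = -(Fp - Fm).ravel() / (2.0 * h)
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    keep = evals > eig_cutoff
    proj = evecs[:, keep].T @ xi
    nonaffine = float(np.sum(proj ** 2 / evals[keep]))
    return float((d2e_dg2 - nonaffine) / n)


def shear_modulus_from_hessian(state: TissueState, params: EnergyParams,
                               H: np.ndarray, fd_step: float = 1e-5,
                               eig_cutoff: float = 1e-10) -> float:
    """Shear modulus reusing a precomputed position Hessian.

    The stress gradient and affine probes are evaluated here (one-sided
    differences for the gradient); the Hessian typically comes from the
    minimizer's Newton polish.
    """
    h = fd_step
    _, sig0 = _forces_and_stress(state, params)
    pos0 = state.positions
    dof = 2 * state.n
    gsig = np.empty(dof)
    for j in range(dof):
        dp = np.zeros_like(pos0)
        dp[j // 2, j % 2] = h
        sp = _forces_and_stress(
            TissueState(pos0 + dp, state.box, state.gamma,
                        seed=state.seed), params)[1]
        gsig[j] = (sp - sig0) / h
    return _modulus_from_parts(state, params, gsig, H, eig_cutoff, h)


def affine_energy_slope(mesh: VoronoiMesh, params: EnergyParams,
                        dg: float = 1e-7) -> float:
    """(1/N) deps/dgamma with the polygon vertices deformed affinely.

    Shears the Voronoi polygons as fixed vertex-model shapes (each vertex
    x -> x + dgamma*y, topology frozen), recomputes the perimeter energy
    and returns the central-difference slope per cell.  Identical to the
    Eq. 9 virial stress: for the perimeter functional,
    deps/dgamma = sum_edges T * lx*ly/L under affine vertex motion.
    Serves as the independent consistency oracle for
    :func:`shear_stress`.
    """
    polys = mesh.cell_polygons

    def energy_at(g):
        e = 0.0
        for p in polys:
            q = p.copy()
            q[:, 0] += g * q[:, 1]
            d = q - np.roll(q, 1, axis=0)
            perim = np.sqrt((d * d).sum(axis=1)).sum()
            e += (params.kappa_A * (_shoelace(q) - 1.0) ** 2
                  + (perim - params.p0) ** 2)
        return e

    return float((energy_at(+dg) - energy_at(-dg)) / (2.0 * dg) / mesh.n)


def _shoelace(q: np.ndarray) -> float:
    x, y = q[:, 0], q[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def finite_difference_modulus(state: TissueState, params: EnergyParams,
                              minimizer, dg: float = 1e-7) -> float:
    """Independent shear-modulus oracle: shear by +-dg, re-minimize, and
    take the symmetric slope of the stress.  ``minimizer`` maps a state to
    its force-balanced relaxation (supplied by the shear-protocol module to
    keep this routine free of circular imports)."""
    sp = minimizer(apply_affine_shear(state, +dg))
    sm = minimizer(apply_affine_shear(state, -dg))
    sig_p = shear_stress(tessellate(sp), params)
    sig_m = shear_stress(tessellate(sm), params)
    return float((sig_p - sig_m) / (2.0 * dg))
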