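"""Athermal quasi-static simple shear: FIRE minimization and the strain
stepping protocol.

Each protocol step applies an affine displacement ``dx_i = dgamma * y_i``
together with the Lees-Edwards image update, then relaxes the tissue to a
force-balanced state with FIRE while the Voronoi topology is rebuilt at
every iteration.  Frames are recorded per strain step; neighbor-exchange
(T1) events are detected between intermediate topology snapshots so each
event carries a minimization-iteration timestamp (the internal clock of an
avalanche).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .geometry import TissueState, _build_geometry, apply_affine_shear
from .mechanics import EnergyParams, _energy_forces_bundle, _mesh_from_bundle, \
    shear_modulus, shear_modulus_from_hessian, shear_stress
from .plasticity import T1Event, detect_t1

logger = logging.getLogger("voroshear")


@dataclass(frozen=True)
class FireConfig:
    """FIRE hyperparameters (canonical values of the original algorithm)."""

    dt_initial: float = 0.02
    dt_max: float = 0.15
    alpha_start: float = 0.1
    f_inc: float = 1.1
    f_dec: float = 0.5
    f_alpha: float = 0.99
    n_min: int = 5


@dataclass(frozen=True)
class ProtocolConfig:
    """Quasi-static shear protocol parameters.

    Defaults follow the reference protocol: strain step 2e-3, residual
    force tolerance 1e-14.  ``gamma_max`` and the steady-state averaging
    window are configurable; desk-scale runs use shorter strain ramps than
    the production value of 6.
    """

    dgamma: float = 2e-3
    gamma_max: float = 6.0
    force_tol: float = 1e-14
    max_iter: int = 500_000
    fire: FireConfig = field(default_factory=FireConfig)
    record_every_k_fire: int = 50
    steady_gamma_min: float = 1.0
    polish: bool = True           # Newton-polish the FIRE tail
    polish_tol: float = 1e-4      # hand over from FIRE to Newton below this
    # Floor acceptance: in the fluid phase the minimum sits on a
    # zero-energy manifold where the residual force is pure roundoff and
    # cannot be driven to force_tol.  A state with energy below eps_floor
    # and residual below res_floor is accepted as converged.
    eps_floor: float = 1e-22
    res_floor: float = 1e-12
    g_every: int = 1              # compute G on every k-th frame (0 = never)
    g_fast: bool = True           # one-sided Hessian differences for G
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dgamma < 1:
            raise ValueError("dgamma must be in [0, 1)")
        if self.force_tol <= 0:
            raise ValueError("force_tol must be positive")
        if self.dgamma > 0 and self.steady_gamma_min >= self.gamma_max:
            raise ValueError("steady_gamma_min must be below gamma_max")


class MinimizationError(RuntimeError):
    def __init__(self, msg, state=None, log=None):
        super().__init__(msg)
        self.state = state
        self.log = log


@dataclass
class FireLog:
    iterations: int
    converged: bool
    residual: float
    energy_initial: float
    energy_final: float
    snapshots: list          # (iteration, adjacency frozenset, positions)
    hessian: np.ndarray | None = None   # FD Hessian from the Newton polish
    hessian_fresh: bool = False         # rebuilt at this state (vs reused)


def _adjacency(bundle) -> frozenset:
    """Unordered base-pair adjacency fingerprint of the current topology."""
    simp = bundle.base[bundle.simplices]
    pairs = np.vstack([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [2, 0]]])
    pairs.sort(axis=1)
    return frozenset(map(tuple, np.unique(pairs, axis=0).tolist()))


def fire_minimize(state: TissueState, params: EnergyParams,
                  config: ProtocolConfig | None = None,
                  record_topology: bool = False,
                  hessian0: np.ndarray | None = None,
                  prerelax: bool = False
                  ) -> tuple[TissueState, FireLog]:
    """Relax a tissue state to force balance with FIRE.

    The Voronoi tessellation is rebuilt at every iteration (the energy is
    always evaluated on the current topology).  With ``record_topology``
    the adjacency fingerprint and positions are snapshotted every
    ``config.record_every_k_fire`` iterations so T1 events inside the
    relaxation can be time-stamped.  ``prerelax`` runs an L-BFGS descent
    first, which is much faster for far-from-minimum initial states (use
    it when relaxing a fresh random tissue, not for small shear probes).

    A state is converged when the residual reaches ``config.force_tol``,
    or when the energy is below ``config.eps_floor`` with residual below
    ``config.res_floor`` (fluid states on the zero-energy manifold, where
    the remaining force is roundoff).

    Raises
    ------
    MinimizationError
        On non-convergence after ``config.max_iter`` iterations; the error
        carries the best state reached and the log.
    """
    config = config or ProtocolConfig()
    f = config.fire
    tol = config.force_tol
    pos = state.positions.copy()
    box, gamma = state.box, state.gamma
    v = np.zeros_like(pos)
    dt = f.dt_initial
    alpha = f.alpha_start
    n_pos = 0
    snapshots = []

    def ef(p):
        b = _build_geometry(TissueState(p, box, gamma, seed=state.seed),
                            check_degenerate=False, with_edges=False)
        eps, F = _energy_forces_bundle(b, params)
        return eps, F, b

    def done(res, eps):
        return res <= tol or (res <= config.res_floor
                              and eps <= config.eps_floor)

    eps0, F, b = ef(pos)
    eps = eps_init = eps0
    if record_topology:
        snapshots.append((0, _adjacency(b), pos.copy()))
    res = float(np.sqrt((F * F).sum(axis=1)).max())
    it = 0
    if prerelax and not done(res, eps):
        pos, eps, F, res = _lbfgs_prerelax(pos, ef)
    hessian = None
    fresh = False
    fire_target = max(tol, config.polish_tol) if config.polish else tol
    while not done(res, eps) and it < config.max_iter:
        # --- FIRE phase (resolves the cascade; snapshots carry the clock)
        while res > fire_target and not done(res, eps) \
                and it < config.max_iter:
            it += 1
            P = float((F * v).sum())
            if P > 0:
                n_pos += 1
                if n_pos > f.n_min:
                    dt = min(dt * f.f_inc, f.dt_max)
                    alpha *= f.f_alpha
            else:
                n_pos = 0
                dt *= f.f_dec
                alpha = f.alpha_start
                v[:] = 0.0
            v += dt * F
            vn = math.sqrt((v * v).sum())
            fn = math.sqrt((F * F).sum())
            if fn > 0 and vn > 0:
                v = (1.0 - alpha) * v + alpha * (vn / fn) * F
            pos = pos + dt * v
            eps, F, b = ef(pos)
            res = float(np.sqrt((F * F).sum(axis=1)).max())
            if record_topology and it % config.record_every_k_fire == 0:
                snapshots.append((it, _adjacency(b), pos.copy()))
        if done(res, eps) or not config.polish:
            break
        # --- Newton polish of the smooth tail
        pos, eps, F, res, hessian, fresh, ok = _newton_polish(
            pos, eps, F, res, ef, tol, H_init=hessian0)
        hessian0 = None
        if not ok:
            # polish rejected (topology motion or soft modes): tighten the
            # FIRE target and keep going with FIRE
            fire_target = max(tol, fire_target * 1e-3)
            hessian = None
    # the Newton polish moves positions without advancing the FIRE clock,
    # so the final snapshot must be keyed on positions, not on ``it``
    if record_topology and (not snapshots
                            or not np.array_equal(snapshots[-1][2], pos)):
        _, _, b = ef(pos)
        snapshots.append((it, _adjacency(b), pos.copy()))

    out = TissueState(pos, box, gamma, seed=state.seed)
    log = FireLog(iterations=it, converged=done(res, eps), residual=res,
                  energy_initial=eps_init, energy_final=eps,
                  snapshots=snapshots, hessian=hessian,
                  hessian_fresh=bool(hessian is not None and fresh))
    if not log.converged:
        raise MinimizationError(
            f"FIRE did not reach residual {tol:g} in {config.max_iter} "
            f"iterations (residual {res:.3e})", state=out, log=log)
    return out, log


def _lbfgs_prerelax(pos, ef, maxiter: int = 50_000):
    """L-BFGS descent to near the minimum (FIRE/Newton finish the tail)."""

    def fun(x):
        eps, F, _b = ef(x.reshape(pos.shape))
        return eps, -F.reshape(-1)

    r = scipy.optimize.minimize(
        fun, pos.reshape(-1), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-20, "gtol": 1e-12,
                 "maxcor": 30})
    pos = r.x.reshape(pos.shape)
    eps, F, _b = ef(pos)
    res = float(np.sqrt((F * F).sum(axis=1)).max())
    return pos, eps, F, res


def _build_fd_hessian(pos, F, ef, h: float = 1e-5) -> np.ndarray:
    """One-sided finite-difference Hessian of the energy (from forces)."""
    n2 = pos.size
    H = np.empty((n2, n2))
    flat = pos.reshape(-1)
    for j in range(n2):
        p = flat.copy()
        p[j] += h
        Fp = ef(p.reshape(pos.shape))[1]
        H[:, j] = -(Fp.reshape(-1) - F.reshape(-1)) / h
    return 0.5 * (H + H.T)


def _newton_polish(pos, eps, F, res, ef, tol, H_init=None, h: float = 1e-5,
                   max_outer: int = 3, eig_floor: float = 1e-8,
                   step_cap: float = 0.5):
    """Quadratic tail convergence via a finite-difference Hessian.

    Solves H dx = F on the subspace of eigenvalues above ``eig_floor`` and
    iterates with the frozen factorization; H comes from ``H_init`` (a
    reusable Hessian from a previous nearby state) or is built by
    one-sided differences of the analytic forces.  A stale H that fails to
    contract triggers a rebuild; a fresh H that fails hands control back
    to FIRE.  Returns (pos, eps, F, res, H, fresh, ok).
    """
    H = H_init
    fresh = False
    for _outer in range(max_outer):
        if H is None:
            H = _build_fd_hessian(pos, F, ef, h)
            fresh = True
        evals, evecs = np.linalg.eigh(H)
        keep = evals > eig_floor
        if not keep.any():
            return pos, eps, F, res, None, False, False
        failed = False
        for _inner in range(8):
            proj = evecs[:, keep].T @ F.reshape(-1)
            dx = (evecs[:, keep] @ (proj / evals[keep])).reshape(pos.shape)
            if np.abs(dx).max() > step_cap:
                failed = True
                break
            scale = 1.0
            for _bt in range(4):
                cand = pos + scale * dx
                eps_c, F_c, _b = ef(cand)
                res_c = float(np.sqrt((F_c * F_c).sum(axis=1)).max())
                if res_c < res:
                    break
                scale *= 0.5
            else:
                failed = True
                break
            pos, eps, F = cand, eps_c, F_c
            contracted = res_c < 0.2 * res
            res = res_c
            if res <= tol:
                return pos, eps, F, res, H, fresh, True
            if not contracted:
                break   # factorization too stale: rebuild
        if failed and fresh:
            return pos, eps, F, res, None, False, False
        H = None         # rebuild on the next outer pass
        fresh = False
    return pos, eps, F, res, None, False, False


def relax(state: TissueState, params: EnergyParams,
          force_tol: float = 1e-14, prerelax: bool = True,
          **kwargs) -> TissueState:
    """Convenience wrapper: minimized copy of ``state``."""
    cfg = ProtocolConfig(force_tol=force_tol, **kwargs)
    return fire_minimize(state, params, cfg, prerelax=prerelax)[0]


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Frame:
    index: int
    gamma: float
    state: TissueState
    energy: float
    sigma: float
    residual: float
    fire_iterations: int
    adjacency: frozenset
    shear_modulus: float = float("nan")


@dataclass
class Trajectory:
    """Strain-indexed sequence of minimized states plus event bookkeeping."""

    params: EnergyParams
    config: ProtocolConfig
    frames: list
    t1_events: list

    @property
    def gammas(self) -> np.ndarray:
        return np.array([f.gamma for f in self.frames])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([f.sigma for f in self.frames])

    @property
    def energies(self) -> np.ndarray:
        return np.array([f.energy for f in self.frames])

    def steady_mask(self, steady_gamma_min: float | None = None) -> np.ndarray:
        g0 = (self.config.steady_gamma_min if steady_gamma_min is None
              else steady_gamma_min)
        return self.gammas >= g0

    def modulus_at(self, index: int) -> float:
        """Instantaneous shear modulus of frame ``index`` (cached)."""
        fr = self.frames[index]
        if math.isnan(fr.shear_modulus):
            fr.shear_modulus = fd_shear_modulus(fr.state, self.params,
                                                self.config)
        return fr.shear_modulus


def fd_shear_modulus(state: TissueState, params: EnergyParams,
                     config: ProtocolConfig | None = None,
                     dg: float = 1e-5,
                     hessian: np.ndarray | None = None) -> float:
    """Shear modulus from the stress slope under re-minimized shear probes.

    Shears by +-dg, re-minimizes (reusing ``hessian`` to make the probe
    relaxations nearly free) and returns the symmetric stress slope.  In
    the fluid phase every edge tension vanishes identically, so this route
    reports a modulus at the numerical noise floor rather than suffering
    the affine/nonaffine cancellation error of the Hessian route, which
    makes it the estimator of choice for solid/fluid classification.

    A state with energy below ``cfg.eps_floor`` is on the zero-energy
    manifold: every tension is zero and remains so under the +-dg probes,
    so G = 0 is returned without probing.
    """
    cfg = config or ProtocolConfig()
    b0 = _build_geometry(state, check_degenerate=False, with_edges=False)
    if _energy_forces_bundle(b0, params)[0] < cfg.eps_floor:
        return 0.0
    out = []
    for s in (+1.0, -1.0):
        probe = apply_affine_shear(state, s * dg)
        rel, _log = fire_minimize(probe, params, cfg,
                                  hessian0=None if hessian is None
                                  else hessian.copy())
        b = _build_geometry(rel, check_degenerate=False, with_edges=True)
        out.append(shear_stress(_mesh_from_bundle(b), params))
    return float((out[0] - out[1]) / (2.0 * dg))


def _frame_observables(state, params):
    b = _build_geometry(state, check_degenerate=False, with_edges=True)
    eps, F = _energy_forces_bundle(b, params)
    mesh = _mesh_from_bundle(b)
    sigma = shear_stress(mesh, params)
    res = float(np.sqrt((F * F).sum(axis=1)).max())
    return b, eps, sigma, res


def run_shear(initial: TissueState, params: EnergyParams,
              config: ProtocolConfig | None = None) -> Trajectory:
    """Drive the athermal quasi-static shear protocol.

    The initial state is relaxed at its current strain, then strain is
    ramped in steps of ``config.dgamma`` up to ``config.gamma_max``; every
    step is affine shear + Lees-Edwards update + FIRE re-minimization.  T1
    events are detected between topology snapshots inside each relaxation.

    On a minimization failure the partial trajectory is attached to the
    raised :class:`MinimizationError`.
    """
    config = config or ProtocolConfig()
    state, log = fire_minimize(initial, params, config, record_topology=True,
                               prerelax=True)
    frames: list[Frame] = []
    events: list[T1Event] = []
    b, eps, sigma, res = _frame_observables(state, params)
    adj = _adjacency(b)
    frames.append(Frame(0, state.gamma, state, eps, sigma, res,
                        log.iterations, adj))
    n_steps = (int(np.floor(config.gamma_max / config.dgamma))
               if config.dgamma > 0 else 0)

    def record_modulus(fr, log):
        fr.shear_modulus = fd_shear_modulus(fr.state, params, config,
                                            hessian=log.hessian)

    if config.g_every:
        record_modulus(frames[0], log)
    # Hessian reuse across elastic steps: the polish accepts a previous H
    # when it still contracts; it is rebuilt on avalanches (contraction
    # failure) and unconditionally every 10 steps to bound drift
    h_prev, h_age = log.hessian, 0
    for k in range(1, n_steps + 1):
        sheared = apply_affine_shear(state, config.dgamma)
        if h_age >= 10:
            h_prev = None
        try:
            state, log = fire_minimize(sheared, params, config,
                                       record_topology=True,
                                       hessian0=h_prev)
        except MinimizationError as err:
            err.trajectory = Trajectory(params, config, frames, events)
            raise
        if log.hessian is not None:
            h_age = 0 if log.hessian_fresh else h_age + 1
            h_prev = log.hessian
        else:
            h_prev, h_age = None, 0
        b, eps, sigma, res = _frame_observables(state, params)
        # prepend the previous frame's adjacency: the affine strain step
        # itself can flip a near-degenerate quad before any FIRE iteration
        snaps = [(0, frames[-1].adjacency, None)] + log.snapshots
        step_events = _events_from_snapshots(snaps, k,
                                             state.box, state.gamma)
        events.extend(step_events)
        adj = log.snapshots[-1][1]
        fr = Frame(k, state.gamma, state, eps, sigma, res,
                   log.iterations, adj)
        if config.g_every and k % config.g_every == 0:
            record_modulus(fr, log)
        frames.append(fr)
        logger.info("step %d gamma=%.4f eps=%.6g sigma=%.6g T1=%d fire=%d",
                    k, state.gamma, eps, sigma, len(step_events),
                    log.iterations)
    return Trajectory(params, config, frames, events)


def _events_from_snapshots(snapshots, strain_index, box, gamma):
    events = []
    for (it0, adj0, _p0), (it1, adj1, p1) in zip(snapshots, snapshots[1:]):
        if adj0 == adj1:
            continue
        evs, _un = detect_t1(adj0, adj1, positions=p1, box=box, gamma=gamma)
        for e in evs:
            e.strain_index = strain_index
            e.fire_time = it1
        events.extend(evs)
    return events


# --------------------------------------------------------------------------
# steady-state observables
# --------------------------------------------------------------------------

def yield_stress(traj: Trajectory, config: ProtocolConfig | None = None,
                 steady_gamma_min: float | None = None) -> float:
    """Steady-state mean shear stress (the quasi-static yield stress).

    Averages sigma over all frames with ``gamma >= steady_gamma_min``.
    """
    cfg = config or traj.config
    g0 = cfg.steady_gamma_min if steady_gamma_min is None else steady_gamma_min
    mask = traj.gammas >= g0
    if not mask.any():
        raise ValueError("trajectory has no frames in the steady regime")
    return float(traj.sigmas[mask].mean())


def noise_floor_crossing(p0_values, ensemble_moduli,
                         g_threshold: float = 1e-8) -> float:
    """p0 at which the ensemble startup modulus reaches its noise floor.

    Takes the midpoint between the last grid point whose ensemble-mean
    modulus exceeds ``g_threshold`` and the first where it does not
    (the rigidity-transition estimate on a p0 grid).
    """
    p0_values = np.asarray(p0_values, float)
    g = np.asarray(ensemble_moduli, float)
    order = np.argsort(p0_values)
    p0_values, g = p0_values[order], g[order]
    above = g > g_threshold
    if above.all() or not above.any():
        raise ValueError("modulus does not cross the noise floor on "
                         "this p0 grid")
    last_above = np.flatnonzero(above)[-1]
    if not above[:last_above + 1].all():
        raise ValueError("non-monotone noise-floor crossing")
    return float(0.5 * (p0_values[last_above] + p0_values[last_above + 1]))


def stress_vanishing_point(p0_values, yield_stresses,
                           tol: float = 1e-4) -> float:
    """First grid p0 at which the yield stress has vanished (below tol)."""
    p0_values = np.asarray(p0_values, float)
    s = np.asarray(yield_stresses, float)
    order = np.argsort(p0_values)
    p0_values, s = p0_values[order], s[order]
    below = np.flatnonzero(s < tol)
    if len(below) == 0:
        raise ValueError("yield stress does not vanish on this p0 grid")
    return float(p0_values[below[0]])


def ensemble_yield_stress(trajs, **kwargs) -> float:
    """Seed-ensemble average of the per-trajectory yield stress."""
    return float(np.mean([yield_stress(t, **kwargs) for t in trajs]))


def solid_fraction(traj: Trajectory, g_threshold: float = 1e-8,
                   steady_gamma_min: float | None = None,
                   stride: int = 1) -> float:
    """Fraction of steady-regime frames with shear modulus above threshold.

    The solid/fluid cut separates the bimodal modulus distribution: the
    fluid peak sits at the numerical noise floor (~1e-12), solids carry a
    finite modulus, so any threshold well between the two works; 1e-8 is
    the geometric midpoint.  Frames without a cached modulus are computed
    on demand (use ``stride`` to subsample for speed).
    """
    idx = np.flatnonzero(traj.steady_mask(steady_gamma_min))[::max(1, stride)]
    if len(idx) == 0:
        raise ValueError("trajectory has no frames in the steady regime")
    g = np.array([traj.modulus_at(int(i)) for i in idx])
    return float(np.mean(g > g_threshold))
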