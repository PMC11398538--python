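"""Seeded synthetic fixtures: lattice and random tissues, edge ensembles.

Everything here is deterministic given the spec (kind + seed + knobs), so
tests and examples need no external data.  ``random_uniform`` reproduces
the strain-free initial condition of the shear protocol: cell centers
drawn uniformly in a box of unit mean cell area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import EdgeEnsemble, TissueState

HEX_SHAPE_INDEX = 6.0 * np.sqrt(2.0 / (3.0 * np.sqrt(3.0)))
"""Shape index of a unit-area regular hexagon, ~3.7224."""

_KINDS = ("random_uniform", "honeycomb", "square", "perturbed_honeycomb",
          "synthetic_edge_ensemble")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int
    seed: int = 0
    noise: float = 0.0            # lattice perturbation scale
    anisotropy: float = 0.0       # edge-ensemble orientation coupling
    driver: float = 0.5           # hidden "stress" driver in [0, 1]
    n_edges: int = 300

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be positive")


def _honeycomb_grid(n: int):
    """nx, ny factorization with even ny and near-square aspect."""
    best = None
    for ny in range(2, n + 1, 2):
        if n % ny:
            continue
        nx = n // ny
        aspect = abs(np.log((nx * 2.0) / (ny * np.sqrt(3.0))))
        if best is None or aspect < best[0]:
            best = (aspect, nx, ny)
    if best is None:
        raise ValueError(f"honeycomb fixture needs n with an even factor, got {n}")
    return best[1], best[2]


def honeycomb_state(n: int, seed: int = 0) -> TissueState:
    """Triangular lattice of cell centers -> regular unit-area hexagons."""
    nx, ny = _honeycomb_grid(n)
    a = np.sqrt(2.0 / np.sqrt(3.0))          # lattice constant, unit cell area
    Lx = nx * a
    Ly = ny * a * np.sqrt(3.0) / 2.0
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (ii + 0.5 * (jj % 2)) * a
    y = (jj + 0.5) * a * np.sqrt(3.0) / 2.0
    pos = np.column_stack([x.ravel(), y.ravel()])
    return TissueState(pos, (Lx, Ly), gamma=0.0, seed=seed)


def square_state(n: int, seed: int = 0) -> TissueState:
    k = int(round(np.sqrt(n)))
    if k * k != n:
        raise ValueError(f"square fixture needs a perfect square n, got {n}")
    L = float(k)
    g = (np.arange(k) + 0.5)
    xx, yy = np.meshgrid(g, g)
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    return TissueState(pos, (L, L), gamma=0.0, seed=seed)


def random_state(n: int, seed: int = 0) -> TissueState:
    L = float(np.sqrt(n))
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, L, size=(n, 2))
    return TissueState(pos, (L, L), gamma=0.0, seed=seed)


def synthetic_edge_ensemble(spec: FixtureSpec) -> EdgeEnsemble:
    """Anisotropic sheared-tissue edge statistics without a simulation.

    Lengths come from a bimodal lognormal mixture (short vs long edges);
    orientations concentrate near 135 deg for short edges and 45 deg for
    long ones.  ``anisotropy`` in [0, 1] scales the orientation coupling
    and ``driver`` plays the role of a hidden stress level: larger driver
    means more short, 135-deg edges (the near-yield phenotype).
    """
    rng = np.random.default_rng(spec.seed)
    aniso = float(np.clip(spec.anisotropy, 0.0, 1.0))
    s = float(np.clip(spec.driver, 0.0, 1.0))
    n = spec.n_edges
    p_short = 0.35 + 0.3 * s
    short = rng.random(n) < p_short
    logl = np.where(short,
                    rng.normal(np.log(0.45), 0.25, n),
                    rng.normal(np.log(1.35), 0.22, n))
    lengths = np.exp(logl)
    center = np.where(short, 135.0, 45.0)
    kappa_spread = 12.0 + 20.0 * s
    von_mises = rng.vonmises(np.radians(2.0 * center), kappa_spread, n)
    concentrated = (np.degrees(von_mises) % 360.0) / 2.0
    uniform = rng.uniform(0.0, 180.0, n)
    use_aniso = rng.random(n) < aniso
    omega = np.where(use_aniso, concentrated, uniform) % 180.0
    return EdgeEnsemble(l=lengths / lengths.mean(), omega=omega, sigma=s)


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; deterministic for a fixed spec."""
    if spec.kind == "random_uniform":
        return random_state(spec.n, spec.seed)
    if spec.kind == "honeycomb":
        return honeycomb_state(spec.n, spec.seed)
    if spec.kind == "square":
        return square_state(spec.n, spec.seed)
    if spec.kind == "perturbed_honeycomb":
        state = honeycomb_state(spec.n, spec.seed)
        rng = np.random.default_rng(spec.seed)
        noise = spec.noise if spec.noise > 0 else 1e-3
        pos = state.positions + rng.normal(0.0, noise, state.positions.shape)
        return TissueState(pos, state.box, gamma=0.0, seed=spec.seed)
    return synthetic_edge_ensemble(spec)
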