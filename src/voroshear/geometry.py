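"""Sheared periodic Voronoi tessellation of a confluent tissue.

The degrees of freedom of the Voronoi vertex model are the cell centers
``r_i`` in a periodic box under Lees-Edwards boundary conditions: the
vertical periodic image is offset horizontally by ``gamma * Ly`` so the
tiling is compatible with an accumulated simple-shear strain ``gamma``.
Cell polygons, areas, perimeters and the cell-cell edge list all derive
from the Voronoi tessellation of the (replicated) cell centers.

Lengths are measured in units of sqrt(A0) with A0 the mean cell area, so
the box area equals the cell number N and the mean cell area is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.spatial import Delaunay, cKDTree


class DegenerateTissueError(ValueError):
    """Raised when generators coincide or the tessellation is ill-posed."""


# --------------------------------------------------------------------------
# tissue state
# --------------------------------------------------------------------------

@dataclass
class TissueState:
    """Cell-center configuration in a Lees-Edwards periodic box.

    Parameters
    ----------
    positions : (N, 2) float array
        Cell centers.  Stored wrapped into the primary sheared cell.
    box : (Lx, Ly)
        Box edge lengths; ``Lx * Ly == N`` (unit mean cell area).
    gamma : float
        Accumulated simple-shear strain.
    seed : int or None
        RNG provenance tag of the initial condition.
    """

    positions: np.ndarray
    box: tuple[float, float]
    gamma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        Lx, Ly = self.box
        if Lx <= 0 or Ly <= 0:
            raise ValueError("box lengths must be positive")
        self.box = (float(Lx), float(Ly))
        self.gamma = float(self.gamma)
        self.positions = wrap_positions(self.positions, self.box, self.gamma)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def box_size(self) -> float:
        """Edge length for a square box (raises if the box is not square)."""
        Lx, Ly = self.box
        if not np.isclose(Lx, Ly):
            raise ValueError("box is not square; use .box")
        return Lx

    def copy(self) -> "TissueState":
        return replace(self, positions=self.positions.copy())


def _le_shift(box: tuple[float, float], gamma: float) -> float:
    """Reduced Lees-Edwards x-offset of the vertical periodic image.

    ``gamma * Ly`` modulo ``Lx``, centered into [-Lx/2, Lx/2): the image
    lattice only depends on this representative, so all imaging uses it
    (accumulated strains well beyond Lx/Ly stay exact).
    """
    Lx, Ly = box
    s = gamma * Ly
    return s - np.round(s / Lx) * Lx


def wrap_positions(positions: np.ndarray, box: tuple[float, float],
                   gamma: float) -> np.ndarray:
    """Wrap into the primary cell honouring the Lees-Edwards offset.

    A point leaving through the top face re-enters at the bottom shifted by
    ``-gamma * Ly`` in x (and vice versa), then x is wrapped mod Lx.
    """
    Lx, Ly = box
    s = _le_shift(box, gamma)
    pos = np.array(positions, dtype=float)
    my = np.floor(pos[:, 1] / Ly)
    pos[:, 1] -= my * Ly
    pos[:, 0] -= my * s
    pos[:, 0] -= np.floor(pos[:, 0] / Lx) * Lx
    return pos


def apply_affine_shear(state: TissueState, dgamma: float) -> TissueState:
    """Apply the affine displacement field ``dx_i = dgamma * y_i`` and
    advance the accumulated strain (Lees-Edwards images follow gamma)."""
    pos = state.positions.copy()
    pos[:, 0] += dgamma * pos[:, 1]
    return TissueState(positions=pos, box=state.box,
                       gamma=state.gamma + dgamma, seed=state.seed)


def minimum_image(disp: np.ndarray, box: tuple[float, float],
                  gamma: float) -> np.ndarray:
    """Minimum-image displacement vectors under the sheared box."""
    Lx, Ly = box
    s = _le_shift(box, gamma)
    d = np.array(disp, dtype=float)
    my = np.round(d[..., 1] / Ly)
    d[..., 1] -= my * Ly
    d[..., 0] -= my * s
    d[..., 0] -= np.round(d[..., 0] / Lx) * Lx
    return d


# --------------------------------------------------------------------------
# tessellation internals
# --------------------------------------------------------------------------

@dataclass
class _GeometryBundle:
    """Everything the energy/force pipeline needs, in flat arrays.

    Incidence rows are (cell, simplex) pairs sorted by cell then by the CCW
    angle of the simplex circumcenter around the cell center, so each cell's
    polygon is a contiguous, ordered slab.
    """

    n: int
    box: tuple[float, float]
    gamma: float
    points: np.ndarray          # (P, 2) primary + ghost coordinates
    base: np.ndarray            # (P,) base cell index of each point
    image_y: np.ndarray         # (P,) vertical image index (for d/dgamma)
    simplices: np.ndarray       # (M, 3) Delaunay simplices into points
    circum: np.ndarray          # (M, 2) circumcenters
    inc_cell: np.ndarray        # (K,) cell index per incidence row
    inc_simplex: np.ndarray     # (K,) simplex index per incidence row
    counts: np.ndarray          # (n,) polygon vertex counts
    starts: np.ndarray          # (n,) slab starts
    nxt: np.ndarray             # (K,) CCW-next row within the cell slab
    prv: np.ndarray             # (K,) CCW-previous row
    areas: np.ndarray           # (n,)
    perimeters: np.ndarray      # (n,)
    # canonical edge table
    edge_i: np.ndarray          # (E,)
    edge_j: np.ndarray          # (E,)
    edge_image: np.ndarray      # (E, 2) image vector of j relative to i
    edge_length: np.ndarray     # (E,)
    edge_angle: np.ndarray      # (E,) orientation in [0, pi)
    edge_vec: np.ndarray        # (E, 2) vector between the two endpoints
    edge_mid: np.ndarray        # (E, 2) midpoint (wrapped)


def _replicate(state: TissueState, margin: float | None):
    """Primary points plus ghost images within ``margin`` of the box."""
    Lx, Ly = state.box
    gamma = state.gamma
    pos = state.positions
    n = pos.shape[0]
    if margin is None:
        # generous bound on the generator-to-Voronoi-vertex reach of a
        # dense tissue; _build_geometry retries with a larger band if a
        # vertex ever falls outside it
        margin = min(2.0, 1.5 * max(Lx, Ly))
    full = 2.0 * margin >= min(Lx, Ly)
    pts = [pos]
    bases = [np.arange(n)]
    imy = [np.zeros(n, dtype=int)]
    for mx in (-1, 0, 1):
        for my in (-1, 0, 1):
            if mx == 0 and my == 0:
                continue
            shift = np.array([mx * Lx + my * _le_shift(state.box, gamma),
                              my * Ly])
            p = pos + shift
            if full:
                keep = np.ones(n, dtype=bool)
            else:
                keep = ((p[:, 0] > -margin) & (p[:, 0] < Lx + margin)
                        & (p[:, 1] > -margin) & (p[:, 1] < Ly + margin))
            if keep.any():
                pts.append(p[keep])
                bases.append(np.flatnonzero(keep))
                imy.append(np.full(keep.sum(), my, dtype=int))
    return (np.concatenate(pts), np.concatenate(bases),
            np.concatenate(imy), margin)


def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    ab = b - a
    ac = c - a
    d2b = (ab * ab).sum(1)
    d2c = (ac * ac).sum(1)
    det = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (ac[:, 1] * d2b - ab[:, 1] * d2c) / det
        uy = (ab[:, 0] * d2c - ac[:, 0] * d2b) / det
    return a + np.column_stack([ux, uy])


def _build_geometry(state: TissueState, margin: float | None = None,
                    check_degenerate: bool = True, with_edges: bool = True,
                    _retry: bool = False) -> _GeometryBundle:
    n = state.n
    pos = state.positions
    Lx, Ly = state.box

    if check_degenerate and n >= 2:
        tree = cKDTree(pos, boxsize=None)
        d, _ = tree.query(pos, k=2)
        if np.min(d[:, 1]) < 1e-12:
            raise DegenerateTissueError(
                "coincident generators (separation < 1e-12)")

    points, base, image_y, used_margin = _replicate(state, margin)
    tri = Delaunay(points)
    simplices = tri.simplices
    # keep simplices incident to at least one primary point
    primary_any = (simplices < n).any(axis=1)
    simplices = simplices[primary_any]
    circum = _circumcenters(points, simplices)

    # incidence rows: (cell, simplex) for primary members only
    m = simplices.shape[0]
    flat = simplices.ravel()
    srep = np.repeat(np.arange(m), 3)
    mask = flat < n
    inc_cell = flat[mask]
    inc_simplex = srep[mask]

    # sanity: the full circumcircle of every simplex used by a primary
    # cell must lie inside the replicated band, otherwise a point outside
    # the band could invalidate the simplex (Delaunay witness missing)
    gen = points[inc_cell]
    cc = circum[inc_simplex]
    if len(inc_cell):
        r = np.hypot(cc[:, 0] - gen[:, 0], cc[:, 1] - gen[:, 1])
        overreach = np.max([
            (-(cc[:, 0] - r)).max() - used_margin,
            (cc[:, 0] + r).max() - Lx - used_margin,
            (-(cc[:, 1] - r)).max() - used_margin,
            (cc[:, 1] + r).max() - Ly - used_margin,
        ])
    else:
        overreach = 0.0
    if not _retry and overreach > -1e-9 and 2 * used_margin < min(Lx, Ly):
        bigger = 2.0 * used_margin + 1.0
        return _build_geometry(state, margin=bigger,
                               check_degenerate=False, with_edges=with_edges,
                               _retry=2 * bigger >= min(Lx, Ly))

    ang = np.arctan2(cc[:, 1] - gen[:, 1], cc[:, 0] - gen[:, 0])
    order = np.lexsort((ang, inc_cell))
    inc_cell = inc_cell[order]
    inc_simplex = inc_simplex[order]

    counts = np.bincount(inc_cell, minlength=n)
    if (counts < 3).any():
        raise DegenerateTissueError(
            "a cell has fewer than 3 Voronoi vertices; "
            "tessellation is degenerate")
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    k = len(inc_cell)
    pos_in = np.arange(k) - starts[inc_cell]
    nxt = starts[inc_cell] + (pos_in + 1) % counts[inc_cell]
    prv = starts[inc_cell] + (pos_in - 1) % counts[inc_cell]

    v = circum[inc_simplex]
    vx, vy = v[:, 0], v[:, 1]
    cross = vx * vy[nxt] - vx[nxt] * vy
    areas = 0.5 * np.bincount(inc_cell, weights=cross, minlength=n)
    seg = v[nxt] - v
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    perimeters = np.bincount(inc_cell, weights=seglen, minlength=n)

    if with_edges:
        edges = _edge_table(n, state, points, base, simplices, circum)
    else:
        z = np.zeros(0)
        edges = dict(edge_i=np.zeros(0, int), edge_j=np.zeros(0, int),
                     edge_image=np.zeros((0, 2), int), edge_length=z,
                     edge_angle=z, edge_vec=np.zeros((0, 2)),
                     edge_mid=np.zeros((0, 2)))

    return _GeometryBundle(
        n=n, box=state.box, gamma=state.gamma, points=points, base=base,
        image_y=image_y, simplices=simplices, circum=circum,
        inc_cell=inc_cell, inc_simplex=inc_simplex, counts=counts,
        starts=starts, nxt=nxt, prv=prv, areas=areas, perimeters=perimeters,
        **edges)


def _edge_table(n, state, points, base, simplices, circum):
    """Canonical cell-cell edge list from Delaunay ridge adjacency.

    A ridge (Voronoi edge) corresponds to a Delaunay edge shared by two
    simplices; its endpoints are the two circumcenters.  Each physical
    ridge is kept once using the convention (min base, max base, image of
    j relative to i), with a lexicographic tie-break on the image vector
    when a cell neighbors its own periodic copy.
    """
    m = simplices.shape[0]
    e0 = simplices[:, [0, 1]]
    e1 = simplices[:, [1, 2]]
    e2 = simplices[:, [2, 0]]
    all_e = np.vstack([e0, e1, e2])
    all_s = np.concatenate([np.arange(m)] * 3)
    all_e.sort(axis=1)
    order = np.lexsort((all_e[:, 1], all_e[:, 0]))
    all_e = all_e[order]
    all_s = all_s[order]
    same = (np.diff(all_e[:, 0]) == 0) & (np.diff(all_e[:, 1]) == 0)
    idx = np.flatnonzero(same)
    pa = all_e[idx, 0]
    pb = all_e[idx, 1]
    s1 = all_s[idx]
    s2 = all_s[idx + 1]

    # require one endpoint primary, and canonical orientation
    Lx, Ly = state.box
    gamma = state.gamma
    prim = pa < n          # pa <= pb so pa primary if any is
    pa, pb, s1, s2 = pa[prim], pb[prim], s1[prim], s2[prim]
    bi = base[pa]
    bj = base[pb]
    # image vector of the pb replica relative to the primary copy of bj
    shift = points[pb] - state.positions[bj]
    le = _le_shift(state.box, gamma)
    mimg_y = np.round(shift[:, 1] / Ly).astype(int)
    mimg_x = np.round((shift[:, 0] - mimg_y * le) / Lx).astype(int)

    keep = (bj > bi) | ((bj == bi) & ((mimg_x > 0)
                                      | ((mimg_x == 0) & (mimg_y > 0))))
    # also keep primary-primary pairs where bi < bj automatically; when
    # both primary, image is (0,0) and bj > bi by sorting of indices
    pa, pb, s1, s2 = pa[keep], pb[keep], s1[keep], s2[keep]
    bi, bj = bi[keep], bj[keep]
    img = np.column_stack([mimg_x[keep], mimg_y[keep]])

    c1 = circum[s1]
    c2 = circum[s2]
    vec = c2 - c1
    length = np.hypot(vec[:, 0], vec[:, 1])
    with np.errstate(invalid="ignore"):
        angle = np.arctan2(vec[:, 1], vec[:, 0]) % np.pi
    angle = np.where(length > 0, angle, 0.0)
    mid = wrap_positions(0.5 * (c1 + c2), state.box, gamma)
    return dict(edge_i=bi, edge_j=bj, edge_image=img, edge_length=length,
                edge_angle=angle, edge_vec=vec, edge_mid=mid)


# --------------------------------------------------------------------------
# public mesh API
# --------------------------------------------------------------------------

@dataclass
class VoronoiMesh:
    """Derived polygonal geometry of a tissue state.

    ``edges`` columns are (i, j, image, length, orientation, midpoint): each
    physical cell-cell interface appears exactly once under the canonical
    periodic-image convention.
    """

    n: int
    box: tuple[float, float]
    gamma: float
    areas: np.ndarray
    perimeters: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_image: np.ndarray
    edge_length: np.ndarray
    edge_angle: np.ndarray
    edge_vec: np.ndarray
    edge_mid: np.ndarray
    _bundle: _GeometryBundle = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edge_length)

    @property
    def cell_polygons(self) -> list[np.ndarray]:
        b = self._bundle
        v = b.circum[b.inc_simplex]
        return [v[b.starts[i]:b.starts[i] + b.counts[i]] for i in range(b.n)]

    @property
    def neighbor_graph(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n)}
        for i, j in zip(self.edge_i, self.edge_j):
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        return adj

    def adjacency_pairs(self) -> set[tuple[int, int]]:
        """Unordered base-index neighbor pairs (topology fingerprint)."""
        return set(zip(self.edge_i.tolist(), self.edge_j.tolist()))

    def n_physical_vertices(self) -> int:
        """Distinct Voronoi vertices of the torus tiling (Euler check)."""
        b = self._bundle
        Lx, Ly = self.box
        le = _le_shift(self.box, self.gamma)
        keys = set()
        for s in b.simplices:
            trip = []
            for p in s:
                bb = int(b.base[p])
                d = b.points[p] - b.points[bb]  # primary copy sits at index bb
                my = int(round(d[1] / Ly))
                mx = int(round((d[0] - my * le) / Lx))
                trip.append((bb, mx, my))
            trip.sort()
            _, mx0, my0 = trip[0]
            keys.add(tuple((bb, mx - mx0, my - my0) for bb, mx, my in trip))
        return len(keys)


def tessellate(state: TissueState, margin: float | None = None) -> VoronoiMesh:
    """Voronoi tessellation of the sheared periodic tissue.

    Ghost images within a safety margin of the box supply the periodic
    neighbors; the margin is enlarged automatically if any Voronoi vertex
    of a primary cell falls outside it.

    Raises
    ------
    DegenerateTissueError
        If two generators coincide within 1e-12 after wrapping.
    """
    b = _build_geometry(state, margin=margin)
    return VoronoiMesh(
        n=b.n, box=b.box, gamma=b.gamma, areas=b.areas,
        perimeters=b.perimeters, edge_i=b.edge_i, edge_j=b.edge_j,
        edge_image=b.edge_image, edge_length=b.edge_length,
        edge_angle=b.edge_angle, edge_vec=b.edge_vec, edge_mid=b.edge_mid,
        _bundle=b)


# --------------------------------------------------------------------------
# edge ensembles (interface to stress inference)
# --------------------------------------------------------------------------

@dataclass
class EdgeEnsemble:
    """Normalized edge lengths and orientations of one snapshot.

    ``l = L / mean(L)`` (dimensionless, mean 1); ``omega`` in degrees in
    [0, 180).  ``gamma``/``sigma`` are optional frame metadata.
    """

    l: np.ndarray
    omega: np.ndarray
    gamma: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        self.l = np.asarray(self.l, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if len(self.l) == 0:
            raise ValueError("edge ensemble is empty")
        if np.any((self.omega < 0) | (self.omega >= 180.0)):
            raise ValueError("orientations must lie in [0, 180) degrees")


def edge_ensemble(mesh: VoronoiMesh, *, drop_zero: bool = True,
                  gamma: float | None = None,
                  sigma: float | None = None) -> EdgeEnsemble:
    """Per-edge (l, omega) with l normalized by the snapshot mean length."""
    L = mesh.edge_length
    ang = mesh.edge_angle
    if drop_zero:
        keep = L > 1e-12
        L, ang = L[keep], ang[keep]
    if len(L) == 0:
        raise ValueError("mesh has no (finite-length) edges")
    return EdgeEnsemble(l=L / L.mean(), omega=np.degrees(ang) % 180.0,
                        gamma=mesh.gamma if gamma is None else gamma,
                        sigma=sigma)
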