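"""Plastic-event analysis: T1 detection, avalanches, statistics, and the
two-point two-time rearrangement correlation field.

A T1 transition is a neighbor exchange among four cells: one cell-cell
adjacency (i, j) vanishes and a new one (k, l) opens between the other
pair of the quad.  An avalanche is the set of T1 events inside a single
quasi-static strain step that relaxes stress — the whole cascade completes
between strain increments, and its internal clock is the FIRE iteration
count at which each topology change was recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import zeta

from .geometry import TissueState, VoronoiMesh, minimum_image, wrap_positions


@dataclass
class T1Event:
    strain_index: int
    fire_time: int
    position: np.ndarray           # midpoint of the exchanged edge
    quad: tuple                    # (i, j, k, l): (i,j) lost, (k,l) gained

    @property
    def lost(self):
        return (self.quad[0], self.quad[1])

    @property
    def gained(self):
        return (self.quad[2], self.quad[3])


@dataclass
class Avalanche:
    events: list
    stress_drop: float
    type: str                      # "I" (fluid precursor) or "II" (solid)
    strain_index: int
    precursor_modulus: float = float("nan")

    @property
    def size(self) -> int:
        return len(self.events)


def _as_pairset(topology) -> tuple[frozenset, frozenset]:
    """Accept an adjacency dict or an iterable of pairs; return the pair
    set and the node id set."""
    if isinstance(topology, dict):
        pairs = {tuple(sorted((i, j))) for i, nbrs in topology.items()
                 for j in nbrs}
        ids = frozenset(topology)
    else:
        pairs = {tuple(sorted(p)) for p in topology}
        ids = frozenset(i for p in pairs for i in p)
    return frozenset(pairs), ids


def detect_t1(topology_before, topology_after, positions=None, box=None,
              gamma: float = 0.0, strain_index: int = 0, fire_time: int = 0):
    """Match lost and gained adjacencies into T1 events.

    Parameters are two neighbor topologies over the same cell ids (dicts
    or pair collections) plus the post-exchange geometry used to place the
    event (midpoint of the gained pair's centers under minimum image).

    Returns ``(events, unmatched)`` where unmatched collects adjacency
    changes that could not be paired into a four-cell exchange.
    """
    before, ids_b = _as_pairset(topology_before)
    after, ids_a = _as_pairset(topology_after)
    if ids_b and ids_a and ids_b != ids_a:
        raise ValueError("topologies are over different cell id sets")
    lost = sorted(before - after)
    gained = sorted(after - before)

    nbr_after: dict = {}
    for i, j in after:
        nbr_after.setdefault(i, set()).add(j)
        nbr_after.setdefault(j, set()).add(i)

    events = []
    unmatched = []
    free_gained = set(gained)
    for (i, j) in lost:
        common = nbr_after.get(i, set()) & nbr_after.get(j, set())
        match = None
        for (k, l) in sorted(free_gained):
            if {k, l} <= common and len({i, j, k, l}) == 4:
                match = (k, l)
                break
        if match is None:
            unmatched.append(("lost", (i, j)))
            continue
        free_gained.discard(match)
        k, l = match
        if positions is not None and box is not None:
            rk = positions[k]
            d = minimum_image(positions[l] - rk, box, gamma)
            pos = wrap_positions((rk + 0.5 * d)[None, :], box, gamma)[0]
        else:
            pos = np.full(2, np.nan)
        events.append(T1Event(strain_index=strain_index, fire_time=fire_time,
                              position=pos, quad=(i, j, k, l)))
    unmatched.extend(("gained", p) for p in sorted(free_gained))
    return events, unmatched


# --------------------------------------------------------------------------
# avalanche segmentation and statistics
# --------------------------------------------------------------------------

def segment_avalanches(traj, g_threshold: float = 1e-8,
                       sigma_drop_floor: float = 1e-6) -> list:
    """One avalanche per strain step with a genuine stress drop and >= 1 T1.

    The avalanche type records the mechanical phase of the precursor
    frame: type II (solid, G above threshold) cascades can transmit
    stress; type I events start from a fluid state.
    """
    by_step: dict[int, list] = {}
    for e in traj.t1_events:
        by_step.setdefault(e.strain_index, []).append(e)
    sig = traj.sigmas
    out = []
    for k in range(1, len(traj.frames)):
        drop = float(sig[k - 1] - sig[k])
        evs = by_step.get(k, [])
        if drop <= sigma_drop_floor or not evs:
            continue
        g_prev = traj.modulus_at(k - 1)
        out.append(Avalanche(
            events=sorted(evs, key=lambda e: e.fire_time),
            stress_drop=drop,
            type="II" if g_prev > g_threshold else "I",
            strain_index=k, precursor_modulus=g_prev))
    return out


@dataclass
class AvalancheStatistics:
    sizes: np.ndarray
    stress_drops: np.ndarray
    mean_size: float
    mean_drop: float
    scaled_drops: np.ndarray       # drops rescaled by their mean

    def size_histogram(self):
        smax = int(self.sizes.max())
        edges = np.arange(1, smax + 2)
        counts, _ = np.histogram(self.sizes, bins=edges)
        return edges[:-1], counts


def avalanche_statistics(avalanches, restrict_to_type_II: bool = False
                         ) -> AvalancheStatistics:
    if restrict_to_type_II:
        avalanches = [a for a in avalanches if a.type == "II"]
    if not avalanches:
        raise ValueError("no avalanches to summarize")
    sizes = np.array([a.size for a in avalanches], dtype=float)
    drops = np.array([a.stress_drop for a in avalanches])
    return AvalancheStatistics(
        sizes=sizes, stress_drops=drops, mean_size=float(sizes.mean()),
        mean_drop=float(drops.mean()), scaled_drops=drops / drops.mean())


# --------------------------------------------------------------------------
# discrete power-law fit (maximum likelihood, zeta-normalized)
# --------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    tau: float                     # exponent, negative sign convention
    tau_se: float                  # bootstrap standard error
    s_min: int
    n_tail: int
    ks_distance: float
    ks_pvalue: float
    good_fit: bool


def _discrete_mle(tail: np.ndarray, s_min: int) -> float:
    """ML estimate of alpha for P(s) = s^-alpha / zeta(alpha, s_min)."""
    logs = np.log(tail).sum()
    n = len(tail)

    def nll(alpha):
        return alpha * logs + n * np.log(zeta(alpha, s_min))

    res = minimize_scalar(nll, bounds=(1.0001, 6.0), method="bounded")
    return float(res.x)


def _ks_stat(tail: np.ndarray, alpha: float, s_min: int) -> float:
    """Sup-norm distance between the empirical and model c.d.f.

    The model c.d.f. F(s) = 1 - zeta(alpha, s+1)/zeta(alpha, s_min) is
    evaluated only at the observed support points (and just below them),
    where the supremum over all integers is attained, so arbitrarily
    heavy-tailed samples stay cheap.
    """
    v = np.unique(tail).astype(float)
    emp = np.searchsorted(np.sort(tail), v, side="right") / len(tail)
    zs = zeta(alpha, s_min)
    F = 1.0 - zeta(alpha, v + 1.0) / zs
    F_below = 1.0 - zeta(alpha, v) / zs          # F(v - 1)
    emp_prev = np.concatenate([[0.0], emp[:-1]])
    return float(max(np.abs(emp - F).max(),
                     np.abs(F_below - emp_prev).max()))


def sample_discrete_power_law(n: int, alpha: float, s_min: int,
                              rng) -> np.ndarray:
    """Exact zeta-distribution draws P(s) ~ s^-alpha on s >= s_min.

    Devroye's rejection sampler for the (untruncated) zeta law, filtered
    to the requested lower cutoff; values are capped at 2^62 (mass far
    below any tolerance used here) to stay within integer range.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    out = np.empty(n, dtype=np.int64)
    filled = 0
    b = 2.0 ** (alpha - 1.0)
    while filled < n:
        m = max(1024, 2 * (n - filled))
        U = rng.random(m)
        V = rng.random(m)
        X = np.floor(U ** (-1.0 / (alpha - 1.0)))
        X = np.minimum(X, 2.0 ** 62)
        T = (1.0 + 1.0 / X) ** (alpha - 1.0)
        accept = V * X * (T - 1.0) / (b - 1.0) <= T / b
        good = X[accept & (X >= s_min)].astype(np.int64)
        take = min(len(good), n - filled)
        out[filled:filled + take] = good[:take]
        filled += take
    return out


def fit_power_law(sizes, s_min: int | None = 1, n_bootstrap: int = 200,
                  n_ks_sim: int = 100, min_tail: int = 100,
                  rng=None) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit of avalanche sizes.

    Reports the exponent as tau < 0 (decaying density convention) with a
    nonparametric-bootstrap standard error.  With ``s_min=None`` the lower
    cutoff is selected by KS-distance minimization; the goodness flag
    compares the observed KS distance against fits of synthetic data drawn
    from the fitted model.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes >= 1]

    def tail_for(m):
        return sizes[sizes >= m].astype(int)

    if s_min is None:
        best = None
        for m in range(1, max(2, int(sizes.max() // 4)) + 1):
            tail = tail_for(m)
            if len(tail) < min_tail:
                break
            a = _discrete_mle(tail, m)
            d = _ks_stat(tail, a, m)
            if best is None or d < best[0]:
                best = (d, m)
        if best is None:
            raise ValueError(f"fewer than {min_tail} values in any tail")
        s_min = best[1]
    tail = tail_for(s_min)
    if len(tail) < min_tail:
        raise ValueError(
            f"need at least {min_tail} values >= s_min, got {len(tail)}")

    alpha = _discrete_mle(tail, s_min)
    ks = _ks_stat(tail, alpha, s_min)

    boots = []
    for _ in range(n_bootstrap):
        resampled = rng.choice(tail, size=len(tail), replace=True)
        boots.append(_discrete_mle(resampled, s_min))
    se = float(np.std(boots, ddof=1))

    worse = 0
    for _ in range(n_ks_sim):
        synth = sample_discrete_power_law(len(tail), alpha, s_min, rng)
        a_s = _discrete_mle(synth, s_min)
        if _ks_stat(synth, a_s, s_min) >= ks:
            worse += 1
    pval = worse / n_ks_sim
    return PowerLawFit(tau=-alpha, tau_se=se, s_min=s_min, n_tail=len(tail),
                       ks_distance=ks, ks_pvalue=pval, good_fit=pval > 0.1)


# --------------------------------------------------------------------------
# two-point two-time correlation field
# --------------------------------------------------------------------------

@dataclass
class CorrelationField:
    """phi(r, dt): conditional probability of a rearrangement at
    displacement r and time lag dt given one at the origin.

    ``phi`` has shape (n_lags, ny, nx); lags are in units of ``time_bin``
    (the topology-recording interval).  ``valid`` flags lags backed by at
    least two events; marginals are normalized per lag.
    """

    lags: np.ndarray
    bin_size: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    phi: np.ndarray
    n_ref: np.ndarray
    valid: np.ndarray

    def marginal_x(self, lag_index: int) -> np.ndarray:
        row = self.phi[lag_index][np.argmin(np.abs(self.y_centers)), :]
        s = row.sum()
        return row / s if s > 0 else row

    def marginal_y(self, lag_index: int) -> np.ndarray:
        col = self.phi[lag_index][:, np.argmin(np.abs(self.x_centers))]
        s = col.sum()
        return col / s if s > 0 else col

    def peak_separation(self, lag_index: int) -> float:
        """Distance between the two maxima of the bimodal x-marginal."""
        px = self.marginal_x(lag_index)
        x = self.x_centers
        left = x < 0
        right = x > 0
        if not left.any() or not right.any():
            return float("nan")
        xl = x[left][np.argmax(px[left])]
        xr = x[right][np.argmax(px[right])]
        return float(xr - xl)

    def fwhm_y(self, lag_index: int) -> float:
        """Full width at half maximum of the y-marginal (interpolated)."""
        return _fwhm(self.y_centers, self.marginal_y(lag_index))


def _fwhm(x, y) -> float:
    if y.max() <= 0:
        return float("nan")
    half = y.max() / 2.0
    above = y >= half
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return float("nan")
    i0, i1 = idx[0], idx[-1]
    # linear interpolation on both shoulders
    if i0 > 0 and y[i0] != y[i0 - 1]:
        xl = x[i0 - 1] + (half - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * (x[i0] - x[i0 - 1])
    else:
        xl = x[i0]
    if i1 < len(y) - 1 and y[i1] != y[i1 + 1]:
        xr = x[i1] + (half - y[i1]) / (y[i1 + 1] - y[i1]) * (x[i1 + 1] - x[i1])
    else:
        xr = x[i1]
    return float(xr - xl)


def correlation_field(events, box, gamma: float = 0.0,
                      lags=(0, 1, 2, 3), bin_size: float = 0.5,
                      extent: float | None = None,
                      time_bin: int = 1) -> CorrelationField:
    """Accumulate phi(r, dt) from T1 events grouped by avalanche.

    Pairs are formed within each strain step (one avalanche per step in
    the quasi-static protocol); displacements use the sheared-box minimum
    image and are mirrored (r and -r both counted), the conditional
    normalization divides by the number of reference events whose
    avalanche extends at least ``dt`` recording intervals past them.
    """
    events = list(events)
    if len(events) < 2:
        raise ValueError("need at least two events")
    lags = np.asarray(lags, dtype=int)
    Lx, Ly = box
    if extent is None:
        extent = min(Lx, Ly) / 2.0
    nbin = int(np.ceil(2 * extent / bin_size))
    edges = -extent + bin_size * np.arange(nbin + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.zeros((len(lags), nbin, nbin))
    n_ref = np.zeros(len(lags))

    by_step: dict[int, list] = {}
    for e in events:
        by_step.setdefault(e.strain_index, []).append(e)

    lag_index = {m: q for q, m in enumerate(lags.tolist())}
    for step_events in by_step.values():
        times = np.array([e.fire_time for e in step_events])
        pos = np.array([e.position for e in step_events])
        tmax = times.max()
        tb = np.maximum(1, time_bin)
        for q, m in enumerate(lags.tolist()):
            n_ref[q] += np.sum(tmax - times >= m * tb) if m > 0 else len(times)
        for a in range(len(step_events)):
            for bidx in range(len(step_events)):
                if a == bidx:
                    continue
                dt_bins = int(round((times[bidx] - times[a]) / tb))
                if dt_bins < 0 or dt_bins not in lag_index:
                    continue
                q = lag_index[dt_bins]
                d = minimum_image(pos[bidx] - pos[a], box, gamma)
                for vec in (d, -d):
                    ix = int((vec[0] + extent) // bin_size)
                    iy = int((vec[1] + extent) // bin_size)
                    if 0 <= ix < nbin and 0 <= iy < nbin:
                        counts[q, iy, ix] += 1.0

    valid = n_ref >= 2
    phi = np.zeros_like(counts)
    for q in range(len(lags)):
        if n_ref[q] > 0:
            phi[q] = counts[q] / n_ref[q]
    phi = np.clip(phi, 0.0, None)
    return CorrelationField(lags=lags, bin_size=bin_size, x_centers=centers,
                            y_centers=centers, phi=np.clip(phi, 0, 1),
                            n_ref=n_ref, valid=valid)


# --------------------------------------------------------------------------
# edge susceptibility and trigger candidates
# --------------------------------------------------------------------------

def edge_susceptibility(length, phi, gamma_dot: float):
    """First-order change in edge length under simple shear:
    dL = gamma_dot * L * sin(2 phi)."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("edge lengths must be positive")
    return gamma_dot * length * np.sin(2.0 * np.asarray(phi))


def most_susceptible_orientation(n_grid: int = 10_000) -> float:
    """Orientation in [0, pi) minimizing dL (maximal shortening).

    Located numerically from the susceptibility itself; equals 3 pi / 4
    for positive simple shear (sin(2 phi) = -1).
    """
    phis = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    coarse = phis[np.argmin(edge_susceptibility(1.0, phis, 1.0))]
    res = minimize_scalar(lambda p: np.sin(2.0 * p),
                          bounds=(coarse - 1e-2, coarse + 1e-2),
                          method="bounded")
    return float(res.x)


def trigger_candidates(mesh: VoronoiMesh, length_quantile: float = 0.1,
                       orientation_window_deg: float = 15.0,
                       gamma_dot: float = 1.0):
    """Short edges aligned with the maximal-shortening orientation.

    Returns indices into the mesh edge table for edges below the given
    length quantile whose orientation lies within the window around
    3 pi / 4, ranked by predicted relative shortening |dL| / L.
    """
    L = mesh.edge_length
    ang = np.degrees(mesh.edge_angle)
    cut = np.quantile(L, length_quantile)
    center = np.degrees(most_susceptible_orientation())
    dist = np.abs((ang - center + 90.0) % 180.0 - 90.0)
    cand = np.flatnonzero((L < cut) & (dist <= orientation_window_deg))
    rate = np.abs(edge_susceptibility(L[cand], mesh.edge_angle[cand],
                                      gamma_dot)) / L[cand]
    return cand[np.argsort(-rate)]
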