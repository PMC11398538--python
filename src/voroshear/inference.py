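"""Edge-statistics stress inference.

A single segmented snapshot of a tissue — just the edge lengths and
orientations, no model parameters — carries information about the shear
stress the tissue sustains.  Under positive simple shear, long edges align
with the extension direction (about 45 degrees) and short edges with the
compression direction (about 135 degrees), so the cumulative distribution
of normalized edge length C(l) and the orientation fraction F(omega)
co-vary with stress.  The value C* = C(l*) at the critical length
l* (where the stress correlation peaks, empirically near 0.61) is a
parameter-free relative stress estimator and an avalanche-risk metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import EdgeEnsemble

DEFAULT_L_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.01), 10)
DEFAULT_OMEGA_GRID = np.arange(0.0, 180.0, 2.0)
DEFAULT_DELTA_OMEGA = 18.0


def cumulative_length(ensemble: EdgeEnsemble,
                      l_grid: np.ndarray | None = None) -> np.ndarray:
    """Empirical c.d.f. of the normalized edge length on ``l_grid``.

    Non-decreasing; reaches 1 at any grid point >= max(l).
    """
    grid = DEFAULT_L_GRID if l_grid is None else np.asarray(l_grid, float)
    l = np.sort(ensemble.l)
    return np.searchsorted(l, grid, side="right") / len(l)


def orientation_fraction(ensemble: EdgeEnsemble, omega: float,
                         delta_omega: float = DEFAULT_DELTA_OMEGA) -> float:
    """Fraction of edges with orientation within ``delta_omega`` of
    ``omega`` (degrees), wrapping around at 0/180."""
    d = np.abs(ensemble.omega - omega) % 180.0
    d = np.minimum(d, 180.0 - d)
    return float(np.mean(d < delta_omega))


def _orientation_fractions(ensemble, omega_grid, delta_omega):
    d = np.abs(ensemble.omega[None, :] - omega_grid[:, None]) % 180.0
    d = np.minimum(d, 180.0 - d)
    return (d < delta_omega).mean(axis=1)


@dataclass
class CorrelationProfile:
    """Stress-correlation scan over the (l, omega) grids.

    ``r_sigma_c[i]`` is the Pearson correlation, across frames, of the
    tissue stress with C(l_grid[i]); ``r_sigma_f`` the same for
    F(omega_grid[j]).  ``c_star`` is the per-frame C(l_star) series.
    """

    l_grid: np.ndarray
    r_sigma_c: np.ndarray
    omega_grid: np.ndarray
    r_sigma_f: np.ndarray
    l_star: float
    omega_star: float
    c_star: np.ndarray
    sigmas: np.ndarray
    max_r_sigma_c: float
    max_r_sigma_f: float


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``x`` with the vector ``y``.

    Columns with zero variance (degenerate c.d.f. values at the grid ends)
    get correlation 0.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    denom = sx * sy
    out = np.zeros(x.shape[1])
    ok = denom > 0
    out[ok] = (xc[:, ok] * yc[:, None]).sum(axis=0) / denom[ok]
    return out


def stress_correlation_scan(frames, l_grid: np.ndarray | None = None,
                            omega_grid: np.ndarray | None = None,
                            delta_omega: float = DEFAULT_DELTA_OMEGA
                            ) -> CorrelationProfile:
    """Correlate tissue stress with C(l) and F(omega) across frames.

    ``frames`` is a sequence of (EdgeEnsemble, sigma) pairs, or of
    EdgeEnsembles carrying ``sigma`` metadata, from one trajectory.
    l_star maximizes R_{sigma,C}; omega_star maximizes R_{sigma,F}.
    Use :func:`ensemble_correlation_scan` to average profiles per seed.
    """
    ensembles, sigmas = _split_frames(frames)
    if len(ensembles) < 10:
        raise ValueError("need at least 10 frames with known stress")
    sigmas = np.asarray(sigmas, float)
    if np.ptp(sigmas) == 0:
        raise ValueError("stress is constant across frames; "
                         "correlation undefined")
    lg = DEFAULT_L_GRID if l_grid is None else np.asarray(l_grid, float)
    og = (DEFAULT_OMEGA_GRID if omega_grid is None
          else np.asarray(omega_grid, float))
    C = np.array([cumulative_length(e, lg) for e in ensembles])
    F = np.array([_orientation_fractions(e, og, delta_omega)
                  for e in ensembles])
    r_c = _pearson_columns(C, sigmas)
    r_f = _pearson_columns(F, sigmas)
    i_star = int(np.argmax(r_c))
    j_star = int(np.argmax(r_f))
    return CorrelationProfile(
        l_grid=lg, r_sigma_c=r_c, omega_grid=og, r_sigma_f=r_f,
        l_star=float(lg[i_star]), omega_star=float(og[j_star]),
        c_star=C[:, i_star], sigmas=sigmas,
        max_r_sigma_c=float(r_c[i_star]), max_r_sigma_f=float(r_f[j_star]))


def ensemble_correlation_scan(trajectories,
                              l_grid: np.ndarray | None = None,
                              omega_grid: np.ndarray | None = None,
                              delta_omega: float = DEFAULT_DELTA_OMEGA
                              ) -> CorrelationProfile:
    """Per-seed correlation profiles averaged, then the maxima located.

    ``trajectories`` is a sequence of frame sequences (one per seed); the
    correlation estimator is computed within each trajectory and the
    R profiles averaged across seeds before taking l_star / omega_star.
    """
    profiles = [stress_correlation_scan(t, l_grid, omega_grid, delta_omega)
                for t in trajectories]
    lg = profiles[0].l_grid
    og = profiles[0].omega_grid
    r_c = np.mean([p.r_sigma_c for p in profiles], axis=0)
    r_f = np.mean([p.r_sigma_f for p in profiles], axis=0)
    i_star = int(np.argmax(r_c))
    j_star = int(np.argmax(r_f))
    l_star = float(lg[i_star])
    c_star = np.concatenate(
        [[cumulative_length(e, np.array([l_star]))[0]
          for e in _split_frames(t)[0]] for t in trajectories])
    sigmas = np.concatenate([p.sigmas for p in profiles])
    return CorrelationProfile(
        l_grid=lg, r_sigma_c=r_c, omega_grid=og, r_sigma_f=r_f,
        l_star=l_star, omega_star=float(og[j_star]), c_star=c_star,
        sigmas=sigmas, max_r_sigma_c=float(r_c[i_star]),
        max_r_sigma_f=float(r_f[j_star]))


def trajectory_edge_frames(traj, steady_gamma_min: float | None = None):
    """Steady-regime (EdgeEnsemble, sigma) pairs of a shear trajectory."""
    from .geometry import edge_ensemble, tessellate

    out = []
    mask = traj.steady_mask(steady_gamma_min)
    for i in np.flatnonzero(mask):
        fr = traj.frames[int(i)]
        ens = edge_ensemble(tessellate(fr.state), gamma=fr.gamma,
                            sigma=fr.sigma)
        out.append((ens, fr.sigma))
    return out


def _split_frames(frames):
    ensembles, sigmas = [], []
    for fr in frames:
        if isinstance(fr, EdgeEnsemble):
            ensembles.append(fr)
            sigmas.append(fr.sigma)
        else:
            e, s = fr
            ensembles.append(e)
            sigmas.append(s)
    return ensembles, sigmas


@dataclass
class LstarEstimate:
    """Stress-free l* estimate from the C(l)-F(omega) cross correlation."""

    l_star: float
    omega_at_max: float
    max_r_cf: float
    l_grid: np.ndarray
    omega_grid: np.ndarray
    r_cf: np.ndarray          # (n_l, n_omega)
    region_mask: np.ndarray


def lstar_without_stress(frames, l_grid: np.ndarray | None = None,
                         omega_grid: np.ndarray | None = None,
                         delta_omega: float = DEFAULT_DELTA_OMEGA,
                         region_quantile: float = 0.99) -> LstarEstimate:
    """Estimate l* without any stress signal.

    Computes the Pearson correlation R_{C(l),F(omega)} across frames for
    every grid pair with l < 1 (short edges carry the compression
    signature), takes the connected region of the correlation matrix above
    its ``region_quantile`` percentile that contains the maximum, and
    returns the region's l-centroid.  Ties between equal maxima break
    toward smaller l.  ``frames`` may be (EdgeEnsemble, sigma) pairs or
    bare ensembles; any stress metadata is ignored.
    """
    ensembles = _split_frames(frames)[0] if not isinstance(
        frames[0], EdgeEnsemble) else list(frames)
    if len(ensembles) < 10:
        raise ValueError("need at least 10 frames")
    lg_all = DEFAULT_L_GRID if l_grid is None else np.asarray(l_grid, float)
    lg = lg_all[lg_all < 1.0]
    og = (DEFAULT_OMEGA_GRID if omega_grid is None
          else np.asarray(omega_grid, float))
    r = _cf_matrix(ensembles, lg, og, delta_omega)
    return _lstar_from_matrix(r, lg, og, region_quantile)


def ensemble_lstar_without_stress(frame_sets,
                                  l_grid: np.ndarray | None = None,
                                  omega_grid: np.ndarray | None = None,
                                  delta_omega: float = DEFAULT_DELTA_OMEGA,
                                  region_quantile: float = 0.99
                                  ) -> LstarEstimate:
    """Stress-free l* from several seeds: per-seed R matrices averaged.

    Mirrors :func:`ensemble_correlation_scan` — the C-F cross correlation
    is estimated within each trajectory (seed-to-seed offsets in the edge
    statistics would otherwise dilute it) and the matrices averaged before
    the region extraction.
    """
    lg_all = DEFAULT_L_GRID if l_grid is None else np.asarray(l_grid, float)
    lg = lg_all[lg_all < 1.0]
    og = (DEFAULT_OMEGA_GRID if omega_grid is None
          else np.asarray(omega_grid, float))
    mats = []
    for frames in frame_sets:
        ensembles = _split_frames(frames)[0] if not isinstance(
            frames[0], EdgeEnsemble) else list(frames)
        if len(ensembles) < 10:
            raise ValueError("need at least 10 frames per seed")
        mats.append(_cf_matrix(ensembles, lg, og, delta_omega))
    r = np.mean(mats, axis=0)
    return _lstar_from_matrix(r, lg, og, region_quantile)


def _cf_matrix(ensembles, lg, og, delta_omega) -> np.ndarray:
    """Pearson correlation of C(l) with F(omega) across a frame sequence."""
    C = np.array([cumulative_length(e, lg) for e in ensembles])
    F = np.array([_orientation_fractions(e, og, delta_omega)
                  for e in ensembles])
    if np.ptp(C, axis=0).max() == 0 or np.ptp(F, axis=0).max() == 0:
        raise ValueError("frames are degenerate (identical edge "
                         "statistics); cross correlation undefined")
    Cc = C - C.mean(axis=0)
    Fc = F - F.mean(axis=0)
    sc = np.sqrt((Cc * Cc).sum(axis=0))
    sf = np.sqrt((Fc * Fc).sum(axis=0))
    num = Cc.T @ Fc
    denom = np.outer(sc, sf)
    r = np.zeros_like(num)
    ok = denom > 0
    r[ok] = num[ok] / denom[ok]
    return r


def _lstar_from_matrix(r: np.ndarray, lg: np.ndarray, og: np.ndarray,
                       region_quantile: float) -> LstarEstimate:
    thresh = np.quantile(r, region_quantile)
    mask = r >= thresh
    labels, _nlab = ndimage.label(mask)
    # maximum of r; ties toward smaller l (row-major argmax does this
    # since rows are ordered by increasing l)
    imax, jmax = np.unravel_index(int(np.argmax(r)), r.shape)
    region = labels == labels[imax, jmax]
    l_star = float(np.mean(lg[np.unique(np.nonzero(region)[0])]))
    return LstarEstimate(
        l_star=l_star, omega_at_max=float(og[jmax]),
        max_r_cf=float(r[imax, jmax]), l_grid=lg, omega_grid=og,
        r_cf=r, region_mask=region)


@dataclass
class RiskCurve:
    """Avalanche-size risk stratified by the C* stress proxy."""

    bin_edges: np.ndarray
    counts: np.ndarray
    p_large: np.ndarray       # P(S >= s_threshold) per bin; NaN if empty
    s_threshold: int
    sizes_per_bin: list = field(default_factory=list)

    def cdf(self, bin_index: int):
        """Empirical c.d.f. of S in one bin: (sorted sizes, cdf values)."""
        s = np.sort(self.sizes_per_bin[bin_index])
        if len(s) == 0:
            return s, s
        return s, np.arange(1, len(s) + 1) / len(s)


def avalanche_risk(pairs, c_star_bins: np.ndarray | None = None,
                   s_threshold: int = 25) -> RiskCurve:
    """Group next-avalanche sizes by the preceding C* level.

    ``pairs`` is a sequence of (c_star, S): the stress proxy of a failure
    state and the size of the avalanche it triggered.  Returns per-bin
    empirical size statistics and P(S >= s_threshold); empty bins are
    flagged with NaN.
    """
    pairs = list(pairs)
    c = np.array([p[0] for p in pairs], float)
    s = np.array([p[1] for p in pairs], float)
    if c_star_bins is None:
        lo, hi = c.min(), c.max()
        pad = 1e-9 * max(1.0, abs(hi))
        c_star_bins = np.linspace(lo - pad, hi + pad, 5)
    edges = np.asarray(c_star_bins, float)
    nb = len(edges) - 1
    counts = np.zeros(nb, int)
    p_large = np.full(nb, np.nan)
    sizes_per_bin = []
    idx = np.clip(np.searchsorted(edges, c, side="right") - 1, 0, nb - 1)
    in_range = (c >= edges[0]) & (c <= edges[-1])
    for b in range(nb):
        sel = s[in_range & (idx == b)]
        sizes_per_bin.append(sel)
        counts[b] = len(sel)
        if len(sel):
            p_large[b] = float(np.mean(sel >= s_threshold))
    return RiskCurve(bin_edges=edges, counts=counts, p_large=p_large,
                     s_threshold=s_threshold, sizes_per_bin=sizes_per_bin)
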