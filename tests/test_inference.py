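import numpy as np
import pytest

from voroshear import (EdgeEnsemble, FixtureSpec, avalanche_risk,
                       cumulative_length, ensemble_lstar_without_stress,
                       lstar_without_stress,
                       orientation_fraction, stress_correlation_scan,
                       synthetic_edge_ensemble)


def _synthetic_frames(n_frames=40, seed0=0, with_sigma=True):
    frames = []
    for i in range(n_frames):
        driver = (i % 11) / 10.0
        ens = synthetic_edge_ensemble(
            FixtureSpec("synthetic_edge_ensemble", 1, seed=seed0 + i,
                        anisotropy=1.0, driver=driver, n_edges=2000))
        frames.append((ens, driver) if with_sigma else ens)
    return frames


def test_cumulative_length_known_values():
    ens = EdgeEnsemble(l=[0.5, 1.0, 1.5], omega=[0.0, 10.0, 20.0])
    C = cumulative_length(ens, np.array([0.4, 0.5, 1.2, 2.0]))
    assert np.allclose(C, [0.0, 1 / 3, 2 / 3, 1.0])
    assert np.all(np.diff(cumulative_length(ens)) >= 0)


def test_cumulative_length_uniform_reference():
    rng = np.random.default_rng(0)
    ens = EdgeEnsemble(l=rng.uniform(0, 2, 100_000),
                       omega=rng.uniform(0, 180, 100_000))
    # uniform lengths on (0, 2): C(l) = l/2, so C(0.61) = 0.305
    C = cumulative_length(ens, np.array([0.61]))
    assert abs(C[0] - 0.305) < 0.005


def test_orientation_fraction():
    rng = np.random.default_rng(1)
    iso = EdgeEnsemble(l=np.ones(200_000),
                       omega=rng.uniform(0, 180, 200_000))
    # window of +-18 deg out of 180 -> fraction 0.2
    assert abs(orientation_fraction(iso, 120.0) - 0.2) < 0.01
    spike = EdgeEnsemble(l=np.ones(10), omega=np.full(10, 10.0))
    assert orientation_fraction(spike, 175.0) == 1.0      # wraps at 0/180
    assert orientation_fraction(spike, 90.0) == 0.0


def test_stress_correlation_scan_finds_signal():
    prof = stress_correlation_scan(_synthetic_frames())
    assert prof.max_r_sigma_c > 0.8
    assert 0.0 < prof.l_star < 1.0
    assert len(prof.c_star) == 40
    # destroying the pairing destroys the correlation
    frames = _synthetic_frames()
    rng = np.random.default_rng(2)
    sig = rng.permutation([s for _, s in frames])
    shuffled = [(e, s) for (e, _), s in zip(frames, sig)]
    prof2 = stress_correlation_scan(shuffled)
    assert prof2.max_r_sigma_c < 0.5


def test_stress_correlation_scan_input_validation():
    frames = _synthetic_frames(n_frames=5)
    with pytest.raises(ValueError):
        stress_correlation_scan(frames)
    const = [(e, 0.3) for e, _ in _synthetic_frames()]
    with pytest.raises(ValueError):
        stress_correlation_scan(const)


def test_lstar_without_stress_matches_hidden_driver_region():
    est = lstar_without_stress(_synthetic_frames(with_sigma=False))
    assert 0.0 < est.l_star < 1.0
    assert est.max_r_cf > 0.8
    assert est.region_mask.any()
    # degenerate input: identical frames
    ens = synthetic_edge_ensemble(
        FixtureSpec("synthetic_edge_ensemble", 1, seed=0, n_edges=500))
    with pytest.raises(ValueError):
        lstar_without_stress([ens] * 12)


def test_ensemble_lstar_without_stress_averages_seeds():
    sets = [_synthetic_frames(with_sigma=False, seed0=100 * k)
            for k in range(3)]
    est = ensemble_lstar_without_stress(sets)
    assert 0.0 < est.l_star < 1.0
    assert est.max_r_cf > 0.8
    # consistent with the single-set estimator on each member
    singles = [lstar_without_stress(s).l_star for s in sets]
    assert abs(est.l_star - np.mean(singles)) < 0.1
    with pytest.raises(ValueError):
        ensemble_lstar_without_stress([sets[0][:5]])


def test_avalanche_risk_bins_and_cdf():
    pairs = [(0.1, 2), (0.15, 3), (0.4, 10), (0.45, 30), (0.8, 60),
             (0.85, 50)]
    curve = avalanche_risk(pairs, c_star_bins=np.array([0.0, 0.3, 0.6,
                                                        0.7, 1.0]),
                           s_threshold=25)
    assert curve.counts.tolist() == [2, 2, 0, 2]
    assert np.isnan(curve.p_large[2])
    assert curve.p_large[0] == 0.0
    assert curve.p_large[1] == 0.5
    assert curve.p_large[3] == 1.0
    s, c = curve.cdf(1)
    assert s.tolist() == [10, 30] and c.tolist() == [0.5, 1.0]
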