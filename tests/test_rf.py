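"""Receptive-field estimation: moment fits, sensitivity maps, effective
gain, shift metrics, and unit sampling."""

import numpy as np
import pytest

from gainscope.network import DTYPE
from gainscope.observer import Observer, ObserverConfig, UnitRef
from gainscope.rf import (FWHM_PER_SIGMA, RFEstimate, SensitivityMap,
                          effective_gain, fit_rf_gaussian, rf_shift_metrics,
                          sample_units, sensitivity_map,
                          unit_position_centers)


def _gaussian_map(side, r0, c0, sigma):
    r = np.arange(side)[:, None]
    c = np.arange(side)[None, :]
    return np.exp(-((r - r0) ** 2 + (c - c0) ** 2) / (2 * sigma**2))


def test_moment_fit_recovers_isotropic_gaussian():
    est = fit_rf_gaussian(_gaussian_map(128, 50, 60, 10.0))
    assert est.center[0] == pytest.approx(50, abs=0.1)
    assert est.center[1] == pytest.approx(60, abs=0.1)
    assert est.fwhm == pytest.approx(FWHM_PER_SIGMA * 10.0, rel=0.01)
    assert est.valid


@pytest.mark.parametrize("sigma", [4.0, 8.0, 16.0])
def test_moment_fit_accuracy_across_sizes(sigma):
    est = fit_rf_gaussian(_gaussian_map(160, 80, 80, sigma))
    assert np.hypot(est.center[0] - 80, est.center[1] - 80) < 0.5
    assert abs(est.fwhm - FWHM_PER_SIGMA * sigma) / (FWHM_PER_SIGMA * sigma) < 0.02


def test_moment_fit_translation():
    m = _gaussian_map(128, 40, 40, 6.0)
    a = fit_rf_gaussian(m)
    b = fit_rf_gaussian(np.roll(m, 5, axis=0))
    assert b.center[0] - a.center[0] == pytest.approx(5, abs=1e-6)
    assert b.center[1] == pytest.approx(a.center[1], abs=1e-6)
    np.testing.assert_allclose(b.covariance, a.covariance, atol=1e-6)


def test_moment_fit_two_point_mass_and_degenerate():
    m = np.zeros((16, 16))
    m[0, 0] = m[0, 10] = 1.0
    est = fit_rf_gaussian(m)
    assert est.center == pytest.approx((0.0, 5.0))
    assert not fit_rf_gaussian(np.zeros((8, 8))).valid


def test_sensitivity_map_of_gaussian_kernel_unit(rng):
    """For a first-block unit whose kernel is a centered 2-D Gaussian, the
    input-gradient sensitivity map is proportional to that Gaussian."""
    cfg = ObserverConfig(input_side=32, channels=(1, 4, 4, 4),
                         kernel_sizes=(9, 3, 3, 3), strides=(1, 1, 1, 1),
                         use_bias=False, seed=0)
    obs = Observer(cfg)
    kern = _gaussian_map(9, 4, 4, 2.0)
    obs.blocks[0][0].W = np.repeat(kern[:, :, None, None], 3, axis=2).astype(DTYPE)
    images = rng.random((8, 32, 32, 3)).astype(np.float32) + 0.5
    side0 = obs.config.block_sides()[0]
    unit = UnitRef(0, 0, side0 // 2, side0 // 2)
    smap = sensitivity_map(obs, unit, images)
    est = fit_rf_gaussian(smap)
    # cosine similarity with the generating Gaussian placed at the fit center
    target = _gaussian_map(32, est.center[0], est.center[1], 2.0)
    cos = (smap.values * target).sum() / np.linalg.norm(smap.values) \
        / np.linalg.norm(target)
    assert cos > 0.99


def test_sensitivity_map_translation_equivariance(small_observer, small_images):
    """Shifting a first-block unit one grid position right moves its
    sensitivity map by the block stride (4 px).  Max-pool selections are
    image-dependent, so the translated maps agree in profile (cosine) rather
    than pixelwise."""
    u1 = UnitRef(0, 2, 7, 7)
    u2 = UnitRef(0, 2, 7, 8)
    m1 = sensitivity_map(small_observer, u1, small_images).values
    m2 = sensitivity_map(small_observer, u2, small_images).values
    rolled = np.roll(m1, 4, axis=1)[:, 8:-8]
    target = m2[:, 8:-8]
    cos = (rolled * target).sum() / np.linalg.norm(rolled) / np.linalg.norm(target)
    assert cos > 0.85
    # the fitted centers differ by the stride along columns
    c1 = fit_rf_gaussian(m1).center
    c2 = fit_rf_gaussian(m2).center
    assert c2[1] - c1[1] == pytest.approx(4.0, abs=1.5)
    assert c2[0] - c1[0] == pytest.approx(0.0, abs=1.5)


def test_dead_unit_yields_zero_map_flagged(small_images):
    """A unit with all-zero incoming weights never responds; its sensitivity
    map is zero and the RF fit is flagged invalid."""
    obs = Observer(ObserverConfig(input_side=64, channels=(8, 16, 16, 16),
                                  seed=7))
    conv = obs.blocks[1][0]
    conv.W[..., 3] = 0.0
    if conv.b is not None:
        conv.b[3] = 0.0
    dead = UnitRef(1, 3, 1, 1)
    smap = sensitivity_map(obs, dead, small_images)
    assert smap.values.sum() == 0
    assert not fit_rf_gaussian(smap).valid


def test_effective_gain():
    base = np.array([1.0, 2.0, 3.0, 5.0])
    assert effective_gain(base, base) == 1.0
    assert effective_gain(base, 2 * base) == 2.0
    assert np.isnan(effective_gain(np.ones(4), base))
    with pytest.raises(ValueError):
        effective_gain(base, base[:2])


def test_rf_shift_metrics_projection():
    rf0 = RFEstimate((10.0, 10.0), np.eye(2), 8.0)
    locus = (10.0, 30.0)
    same = rf_shift_metrics(rf0, rf0, locus)
    assert (same.shift_toward_locus, same.shift_pct, same.size_change) == \
        (0.0, 0.0, 1.0)
    toward = rf_shift_metrics(rf0, RFEstimate((10.0, 15.0), np.eye(2), 8.0),
                              locus)
    assert toward.shift_toward_locus == pytest.approx(5.0)
    assert toward.shift_pct == pytest.approx(62.5)
    ortho = rf_shift_metrics(rf0, RFEstimate((15.0, 10.0), np.eye(2), 8.0),
                             locus)
    assert ortho.shift_toward_locus == pytest.approx(0.0, abs=1e-9)
    shrunk = rf_shift_metrics(rf0, RFEstimate((10.0, 10.0), np.eye(2), 4.0),
                              locus)
    assert shrunk.size_change == pytest.approx(0.5)


def test_sample_units_density_and_determinism(small_observer):
    locus = (15.5, 15.5)
    u1 = sample_units(small_observer, 40, locus, seed=5)
    u2 = sample_units(small_observer, 40, locus, seed=5)
    assert u1 == u2
    assert len(u1) == 160  # 40 per block x 4 blocks
    # sampled units sit closer to the locus than the uniform average
    for b in range(4):
        centers = unit_position_centers(small_observer, b)
        d_all = np.hypot(centers[..., 0] - locus[0],
                         centers[..., 1] - locus[1]).mean()
        sampled = [u for u in u1 if u.block == b]
        d_s = np.mean([np.hypot(centers[u.row, u.col, 0] - locus[0],
                                centers[u.row, u.col, 1] - locus[1])
                       for u in sampled])
        assert d_s < d_all
    with pytest.raises(ValueError):
        sample_units(small_observer, 10**6, locus, seed=0)
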