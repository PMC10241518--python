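"""Counterfactual rewiring: shift maps, kernel restructuring, shrinkage."""

import numpy as np
import pytest

from gainscope.attention import GainField, field_for_quadrant
from gainscope.rewire import (ShiftMap, build_shift_map,
                              make_shift_only_observer, restructure_kernels,
                              shrink_rewire, shrinkage_factor)
from gainscope.observer import UnitRef
from gainscope.rf import fit_rf_gaussian, sensitivity_map


# -- shift map --------------------------------------------------------------

def test_build_shift_map_constant_and_zero():
    centers = np.random.default_rng(0).uniform(0, 32, (25, 2))
    zero = build_shift_map(centers, np.zeros((25, 2)), (32, 32), k=5,
                           blur_sigma=2.0)
    np.testing.assert_allclose(zero.dr, 0.0)
    const = build_shift_map(centers, np.tile([2.0, -1.0], (25, 1)), (32, 32),
                            k=5, blur_sigma=2.0)
    np.testing.assert_allclose(const.dr, 2.0, atol=1e-9)
    np.testing.assert_allclose(const.dc, -1.0, atol=1e-9)


def test_build_shift_map_inverse_distance_weighting():
    centers = np.array([[0.0, 2.0], [0.0, -2.0]])
    shifts = np.array([[2.0, 0.0], [0.0, 0.0]])
    sm = build_shift_map(centers, shifts, (1, 1), k=2, blur_sigma=0.0)
    # query pixel (0,0) is equidistant: plain average
    assert sm.dr[0, 0] == pytest.approx(1.0)
    assert sm.dc[0, 0] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        build_shift_map(centers, shifts, (4, 4), k=5)


def test_shift_only_zero_map_is_identity(small_observer, small_images):
    sm = ShiftMap(np.zeros((64, 64)), np.zeros((64, 64)))
    variant = make_shift_only_observer(small_observer, sm)
    np.testing.assert_array_equal(variant.forward(small_images).final_map,
                                  small_observer.forward(small_images).final_map)


def test_shift_only_constant_shift_moves_rf(small_observer, small_images):
    """A constant shift map displaces measured last-block RF centers by
    about the applied shift."""
    delta = 8.0
    sm = ShiftMap(np.full((64, 64), delta), np.zeros((64, 64)))
    variant = make_shift_only_observer(small_observer, sm)
    moved_r, moved_c = [], []
    for ch in range(3):
        unit = UnitRef(3, ch, 1, 1)
        rf0 = fit_rf_gaussian(sensitivity_map(small_observer, unit, small_images))
        rf1 = fit_rf_gaussian(sensitivity_map(variant, unit, small_images))
        if rf0.valid and rf1.valid:
            moved_r.append(rf1.center[0] - rf0.center[0])
            moved_c.append(rf1.center[1] - rf0.center[1])
    assert moved_r, "no responsive last-block units"
    # moment estimates of these broad RFs under-report the shift (mass is
    # clipped at the image border), so test direction and rough magnitude
    assert 0.4 * delta <= np.mean(moved_r) <= 1.3 * delta
    assert abs(np.mean(moved_c)) < 0.3 * delta


# -- structure --------------------------------------------------------------

def test_restructure_beta_one_is_identity(small_observer, small_images):
    variant = restructure_kernels(small_observer,
                                  field_for_quadrant(64, "NW", 1.0))
    np.testing.assert_allclose(variant.forward(small_images).final_map,
                               small_observer.forward(small_images).final_map,
                               atol=1e-5)


def test_restructure_preserves_kernel_l2(small_observer):
    variant = restructure_kernels(small_observer,
                                  field_for_quadrant(64, "NW", 4.0))
    for b in range(4):
        conv = small_observer.blocks[b][0]
        lc = variant.blocks[b][0]
        # fully interior output position: all taps read real input
        i = lc.W.shape[0] // 2
        n_orig = (conv.W.astype(np.float64) ** 2).sum(axis=(0, 1, 2))
        n_new = (lc.W[i, i].astype(np.float64) ** 2).sum(axis=(0, 1, 2))
        np.testing.assert_allclose(n_new, n_orig, rtol=1e-6)


def test_restructure_uniform_gain_cancels(small_observer, small_images):
    """Gain constant across every kernel's support (sigma -> infinity) is
    removed entirely by the L2 rescale."""
    wide = GainField(15.5, 15.5, 1e7, 4.0)
    variant = restructure_kernels(small_observer, wide)
    np.testing.assert_allclose(variant.forward(small_images).final_map,
                               small_observer.forward(small_images).final_map,
                               rtol=1e-4, atol=1e-5)


# -- shrinkage --------------------------------------------------------------

def test_shrinkage_factor_closed_form():
    assert shrinkage_factor(0.0, 0.0) == 1.0
    assert shrinkage_factor(0.0, 0.4) == pytest.approx(0.6)
    assert shrinkage_factor(5 * 112.0, 0.4) == pytest.approx(1.0, abs=1e-3)
    d = np.linspace(0, 600, 50)
    f = shrinkage_factor(d, 0.4)
    assert np.all(f > 0) and np.all(f <= 1.4)
    with pytest.raises(ValueError):
        shrinkage_factor(-1.0, 0.2)
    with pytest.raises(ValueError):
        shrinkage_factor(1.0, 1.2)


def test_shrink_beta_zero_reproduces_convolution(small_observer, small_images):
    variant = shrink_rewire(small_observer, 0.0, (15.5, 15.5))
    np.testing.assert_allclose(variant.forward(small_images).final_map,
                               small_observer.forward(small_images).final_map,
                               atol=1e-5)


def test_shrink_conserves_tap_mass(small_observer):
    """Bilinear splitting partitions unity, so each locally connected kernel
    carries the same total weight as the original 3x3 kernel."""
    variant = shrink_rewire(small_observer, 0.4, (15.5, 15.5))
    lc = variant.blocks[3][0]
    conv = small_observer.blocks[3][0]
    total_orig = conv.W.astype(np.float64).sum(axis=(0, 1))
    for i in range(lc.W.shape[0]):
        for j in range(lc.W.shape[1]):
            np.testing.assert_allclose(
                lc.W[i, j].astype(np.float64).sum(axis=(0, 1)), total_orig,
                rtol=1e-4, atol=1e-6)


def test_shrink_reduces_rf_size_near_locus(small_observer, small_images):
    locus = (15.5, 15.5)
    variant = shrink_rewire(small_observer, 0.4, locus)
    ratios, shifts = [], []
    for ch in range(4):
        unit = UnitRef(3, ch, 0, 0)  # NW unit, nearest the locus
        rf0 = fit_rf_gaussian(sensitivity_map(small_observer, unit, small_images))
        rf1 = fit_rf_gaussian(sensitivity_map(variant, unit, small_images))
        if rf0.valid and rf1.valid and rf0.fwhm > 0:
            ratios.append(rf1.fwhm / rf0.fwhm)
            shifts.append(np.hypot(rf1.center[0] - rf0.center[0],
                                   rf1.center[1] - rf0.center[1]))
    fwhms = [fit_rf_gaussian(sensitivity_map(small_observer,
                                             UnitRef(3, ch, 0, 0),
                                             small_images)).fwhm
             for ch in range(4)]
    assert ratios, "no responsive NW units"
    assert np.mean(ratios) < 1.0
    # position is preserved up to moment-fit noise (well under the RF size)
    assert np.mean(shifts) < 0.15 * np.nanmean(fwhms)
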