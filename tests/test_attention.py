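"""Attention fields: Gaussian/flat gain maps, quadrant isolation, normalized
exponentiation, and output-gain application."""

import numpy as np
import pytest

from gainscope.attention import (GainField, QuadrantIsolatedObserver,
                                 apply_output_gain, field_for_quadrant,
                                 flat_quadrant_gain, gaussian_gain_map,
                                 normalized_exponentiation,
                                 propagated_gain_map, quadrant_center)
from gainscope.observer import UnitRef


def test_gaussian_gain_closed_form():
    f = GainField(100.0, 100.0, 56.0, 4.0)
    g = gaussian_gain_map(f, (224, 224))
    assert g[100, 100] == pytest.approx(4.0)
    # point at distance sigma from the center: (beta-1) e^{-1/2} + 1
    assert g[100, 156] == pytest.approx(3.0 * np.exp(-0.5) + 1.0, rel=1e-9)
    assert g.min() >= 1.0 and g.max() <= 4.0
    # radially monotone from the peak
    ray = g[100, 100:]
    assert np.all(np.diff(ray) <= 0)


def test_gain_field_validation():
    with pytest.raises(ValueError):
        GainField(0, 0, 56.0, 0.9)
    with pytest.raises(ValueError):
        GainField(0, 0, -1.0, 2.0)
    assert gaussian_gain_map(GainField(5, 5, 3.0, 1.0), (16, 16)) \
        == pytest.approx(1.0)


def test_quadrant_center_convention():
    assert quadrant_center(224, "NW") == (55.5, 55.5)
    assert quadrant_center(224, "SE") == (167.5, 167.5)
    assert quadrant_center(64, "NE") == (15.5, 47.5)


def test_flat_quadrant_gain_matches_numeric_mean():
    f = field_for_quadrant(224, "NW", beta=4.0, sigma=56.0)
    flat = flat_quadrant_gain(f, "NW", (224, 224))
    # independent oracle: evaluate the field formula directly on the grid
    total = 0.0
    for r in range(112):
        c = np.arange(112, dtype=float)
        total += np.sum((4 - 1) * np.exp(-((r - 55.5) ** 2 + (c - 55.5) ** 2)
                                         / (2 * 56.0**2)) + 1)
    assert flat[0, 0] == pytest.approx(total / 112**2, rel=1e-12)
    assert set(np.unique(flat)) == {1.0, flat[0, 0]}
    assert flat_quadrant_gain(GainField(55.5, 55.5, 56.0, 1.0), "NW",
                              (224, 224)) == pytest.approx(1.0)


def test_quadrant_isolation_contract(small_observer, small_images):
    """Perturbing every NE-quadrant pixel leaves all NW-assigned outputs
    bit-identical, at every block."""
    iso = QuadrantIsolatedObserver(small_observer)
    x = small_images.copy()
    base = iso.forward(x)
    x2 = x.copy()
    x2[:, :32, 32:, :] = np.random.default_rng(0).random((len(x), 32, 32, 3))
    pert = iso.forward(x2)
    for a, b in zip(base.block_outputs, pert.block_outputs):
        h = a.shape[1] // 2
        np.testing.assert_array_equal(a[:, :h, :h], b[:, :h, :h])  # NW
        np.testing.assert_array_equal(a[:, h:, :h], b[:, h:, :h])  # SW
        np.testing.assert_array_equal(a[:, h:, h:], b[:, h:, h:])  # SE
        assert not np.array_equal(a[:, :h, h:], b[:, :h, h:])      # NE changed


def test_quadrant_isolation_equals_standalone_quadrant_pass(small_observer,
                                                            small_images):
    iso = QuadrantIsolatedObserver(small_observer)
    acts = iso.forward(small_images)
    # run the NW quadrant alone through the same blocks
    x = small_images[:, :32, :32, :]
    for block in small_observer.blocks:
        for layer in block:
            x = layer.forward(x)
    h = acts.final_map.shape[1] // 2
    np.testing.assert_array_equal(acts.final_map[:, :h, :h], x)


def test_quadrant_isolated_gradient_stays_in_quadrant(small_observer,
                                                      small_images):
    iso = QuadrantIsolatedObserver(small_observer)
    side = iso.forward(small_images[:2]).final_map.shape[1]
    h = side // 2
    unit = UnitRef(3, 0, h, h)  # an SE-quadrant unit
    grad = iso.unit_gradient(small_images[:2], unit)
    assert np.abs(grad[:, :32, :, :]).sum() == 0
    assert np.abs(grad[:, :, :32, :]).sum() == 0


def test_normalized_exponentiation_properties(rng):
    a = rng.random((5, 6, 4)).astype(np.float32)
    np.testing.assert_allclose(normalized_exponentiation(a, 1.0), a, rtol=1e-6)
    const = np.full((3, 3, 2), 1.7, np.float32)
    np.testing.assert_allclose(normalized_exponentiation(const, 3.0), const,
                               rtol=1e-5)
    b = normalized_exponentiation(np.array([[[1.0], [2.0]]]), 2.0)
    np.testing.assert_allclose(b.ravel(), [0.6, 2.4], rtol=1e-6)
    # L1 mass conservation
    for xi in (1.5, 2.0, 3.8):
        out = normalized_exponentiation(a, xi)
        assert np.abs(out).sum() == pytest.approx(np.abs(a).sum(), rel=1e-5)
    zeros = np.zeros((4, 4, 2), np.float32)
    np.testing.assert_array_equal(normalized_exponentiation(zeros, 2.0), zeros)
    with pytest.raises(ValueError):
        normalized_exponentiation(a, 0.5)


def test_apply_output_gain(rng):
    fm = rng.random((3, 4, 4, 5)).astype(np.float32)
    gm = 1.0 + rng.random((4, 4))
    out = apply_output_gain(fm, gm, "multiply")
    back = apply_output_gain(out, gm, "divide")
    np.testing.assert_allclose(back, fm, rtol=1e-5)
    np.testing.assert_allclose(apply_output_gain(fm, np.ones((4, 4)),
                                                 "multiply"), fm)
    with pytest.raises(ValueError):
        apply_output_gain(fm, np.zeros((4, 4)), "divide")
    with pytest.raises(ValueError):
        apply_output_gain(fm, gm[:2, :2], "multiply")
    with pytest.raises(ValueError):
        apply_output_gain(fm, gm, "add")


def test_flattened_readout_representation(small_observer, small_images):
    """The unpooled readout keeps the spatial layout: flattened encodings
    have (positions x channels) length, and the full-map keep mask with mean
    pooling reproduces the standard encoding exactly."""
    from gainscope.observer import batched_encode

    fm = small_observer.forward(small_images).final_map
    h, w, c = fm.shape[1:]
    flat = batched_encode(small_observer, small_images, flatten=True)
    assert flat.shape == (len(small_images), h * w * c)
    full_mask = np.ones((h, w), bool)
    pooled = batched_encode(small_observer, small_images, keep_mask=full_mask)
    np.testing.assert_allclose(pooled,
                               small_observer.forward(small_images).encoding,
                               rtol=1e-6)


def test_propagated_gain_map_homogeneity(small_observer_nobias, small_images):
    """No gain -> map of ones; a flat full-field gain k propagates to a
    constant map of k in a bias-free model."""
    ones = propagated_gain_map(small_observer_nobias, np.ones((64, 64)),
                               small_images)
    np.testing.assert_allclose(ones, 1.0, rtol=1e-5)
    k = 3.0
    const = propagated_gain_map(small_observer_nobias, np.full((64, 64), k),
                                small_images)
    np.testing.assert_allclose(const, k, rtol=1e-4)
    with pytest.raises(ValueError):
        propagated_gain_map(small_observer_nobias, np.ones((64, 64)),
                            small_images[:0])
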