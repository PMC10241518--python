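"""Gradient-based receptive-field estimation and gain metrics.

A unit's receptive field (RF) is estimated from its input-gradient
sensitivity map: the magnitude of d(activation)/d(pixel) is summed over
color channels and averaged over a batch of task images, and the resulting
non-negative map is treated as an unnormalized 2-D density whose mean and
covariance define a Gaussian RF.  RF size is reported as the full width at
half maximum, FWHM = 2 sqrt(2 ln 2) sigma, scalarized as the mean of the
per-axis FWHMs from the covariance eigenvalues.

Effective gain of a unit is the ratio of the standard deviation of its
activity across stimuli with an attention manipulation versus without.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import DTYPE
from .observer import Observer, UnitRef

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_MIN_MASS = 1e-8


@dataclass
class SensitivityMap:
    values: np.ndarray          # (H, W), >= 0
    unit: UnitRef
    n_images: int

    @property
    def mass(self) -> float:
        return float(self.values.sum())


@dataclass
class RFEstimate:
    center: tuple               # (row, col), px
    covariance: np.ndarray      # 2x2, px^2
    fwhm: float                 # px
    valid: bool = True


def sensitivity_map(model, unit: UnitRef, images, gain_map=None) -> SensitivityMap:
    """Per-pixel gradient magnitude of one unit, summed over RGB and averaged
    over the image batch.  ``model`` is anything exposing
    ``unit_gradient(images, unit, gain_map=...)`` (plain observer,
    quadrant-isolated wrapper, or a rewired variant)."""
    images = np.asarray(images, DTYPE)
    if images.ndim == 3:
        images = images[None]
    if len(images) == 0:
        raise ValueError("sensitivity map needs at least one image")
    grads = model.unit_gradient(images, unit, gain_map=gain_map)
    values = np.abs(grads.astype(np.float64)).sum(axis=3).mean(axis=0)
    return SensitivityMap(values, unit, len(images))


def sensitivity_maps(model, units: Sequence[UnitRef], images,
                     gain_map=None) -> list:
    """Sensitivity maps for many units, sharing one forward pass when the
    model supports batched gradients."""
    images = np.asarray(images, DTYPE)
    if images.ndim == 3:
        images = images[None]
    if hasattr(model, "unit_gradients"):
        out = []
        for start in range(0, len(units), 16):   # chunk to bound memory
            chunk = list(units[start:start + 16])
            grads = model.unit_gradients(images, chunk, gain_map=gain_map)
            out.extend(
                SensitivityMap(np.abs(g.astype(np.float64)).sum(axis=3).mean(axis=0),
                               u, len(images))
                for u, g in zip(chunk, grads))
        return out
    return [sensitivity_map(model, u, images, gain_map) for u in units]


def fit_rf_gaussian(smap) -> RFEstimate:
    """Moment fit: mass-weighted mean and second central moments of the
    sensitivity map; a (near-)zero-mass map yields ``valid=False``."""
    values = smap.values if isinstance(smap, SensitivityMap) else np.asarray(smap, float)
    mass = values.sum()
    if not np.isfinite(mass) or mass <= _MIN_MASS:
        return RFEstimate((np.nan, np.nan), np.full((2, 2), np.nan), np.nan,
                          valid=False)
    H, W = values.shape
    r = np.arange(H, dtype=float)
    c = np.arange(W, dtype=float)
    p_r = values.sum(axis=1) / mass
    p_c = values.sum(axis=0) / mass
    mu_r = float(r @ p_r)
    mu_c = float(c @ p_c)
    var_r = float(((r - mu_r) ** 2) @ p_r)
    var_c = float(((c - mu_c) ** 2) @ p_c)
    cov_rc = float((values * np.outer(r - mu_r, c - mu_c)).sum() / mass)
    cov = np.array([[var_r, cov_rc], [cov_rc, var_c]])
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    fwhm = FWHM_PER_SIGMA * float(np.mean(np.sqrt(eig)))
    return RFEstimate((mu_r, mu_c), cov, fwhm, valid=True)


def effective_gain(activations_base, activations_attn) -> float:
    """std(attn) / std(base) across the same stimuli; NaN when the baseline
    has zero variance (flagged undefined)."""
    base = np.asarray(activations_base, np.float64)
    attn = np.asarray(activations_attn, np.float64)
    if base.shape != attn.shape:
        raise ValueError("activation series must have matching lengths")
    sb = base.std()
    if sb == 0:
        return float("nan")
    return float(attn.std() / sb)


@dataclass
class RFShiftMetrics:
    shift_toward_locus: float   # px, positive = toward the locus
    shift_pct: float            # shift as % of baseline FWHM
    size_change: float          # fwhm_attn / fwhm_base
    displacement: tuple = (0.0, 0.0)


def rf_shift_metrics(rf_base: RFEstimate, rf_attn: RFEstimate, locus) -> RFShiftMetrics:
    """Shift projected onto the unit-to-locus direction, shift as a percent
    of the baseline FWHM, and the FWHM ratio."""
    if not (rf_base.valid and rf_attn.valid):
        return RFShiftMetrics(np.nan, np.nan, np.nan)
    d = np.array(rf_attn.center) - np.array(rf_base.center)
    to_locus = np.array(locus, float) - np.array(rf_base.center)
    norm = np.linalg.norm(to_locus)
    if norm == 0:
        toward = float(np.linalg.norm(d))
    else:
        toward = float(d @ (to_locus / norm))
    pct = 100.0 * toward / rf_base.fwhm if rf_base.fwhm > 0 else np.nan
    size = rf_attn.fwhm / rf_base.fwhm if rf_base.fwhm > 0 else np.nan
    return RFShiftMetrics(toward, pct, size, tuple(d))


# ---------------------------------------------------------------------------
# unit sampling and population tables
# ---------------------------------------------------------------------------

def unit_position_centers(observer: Observer, block: int) -> np.ndarray:
    """Image-space centers of a block's spatial grid positions, (side, side, 2)."""
    side = observer.config.block_sides()[block]
    scale = observer.config.input_side / side
    centers = (np.arange(side) + 0.5) * scale - 0.5
    rr, cc = np.meshgrid(centers, centers, indexing="ij")
    return np.stack([rr, cc], axis=-1)


def sample_units(observer: Observer, per_layer_n: int, locus, seed: int = 0,
                 blocks: Optional[Sequence[int]] = None) -> list:
    """Seed-deterministic unit sample with density decreasing with distance
    from the locus: p ∝ exp(-d / lambda), lambda = image_side / 4."""
    blocks = list(blocks) if blocks is not None else list(range(len(observer.blocks)))
    lam = observer.config.input_side / 4.0
    rng = np.random.default_rng([seed, 31])
    units = []
    for b in blocks:
        side = observer.config.block_sides()[b]
        n_ch = observer.config.channels[b]
        total = side * side * n_ch
        if per_layer_n > total:
            raise ValueError(f"block {b} has {total} units < {per_layer_n} requested")
        centers = unit_position_centers(observer, b).reshape(-1, 2)
        d = np.hypot(centers[:, 0] - locus[0], centers[:, 1] - locus[1])
        p_pos = np.exp(-d / lam)
        p = np.repeat(p_pos, n_ch)
        p = p / p.sum()
        flat = rng.choice(total, size=per_layer_n, replace=False, p=p)
        for f in flat:
            pos, ch = divmod(int(f), n_ch)
            r, c = divmod(pos, side)
            units.append(UnitRef(b, ch, r, c))
    return units


def unit_activation_series(model, units: Sequence[UnitRef], images,
                           gain_map=None, batch_size: int = 64) -> np.ndarray:
    """(n_units, n_images) activations collected from the block outputs."""
    images = np.asarray(images, DTYPE)
    series = np.empty((len(units), len(images)))
    for start in range(0, len(images), batch_size):
        acts = model.forward(images[start:start + batch_size], gain_map=gain_map)
        for ui, u in enumerate(units):
            series[ui, start:start + batch_size] = \
                acts.block_outputs[u.block][:, u.row, u.col, u.channel]
    return series


def rf_population_table(base_model, attn_model, units: Sequence[UnitRef],
                        images, locus, gain_map_base=None, gain_map_attn=None,
                        condition: str = "") -> pd.DataFrame:
    """Per-unit RF and gain comparison between a baseline and an attention
    condition.

    The two conditions may differ by a gain map (Gaussian-gain model), by the
    model itself (rewired counterfactuals), or both.  Units whose sensitivity
    map mass falls below threshold in either condition are flagged invalid
    and excluded from population statistics by the caller.
    """
    act_b = unit_activation_series(base_model, units, images, gain_map_base)
    act_a = unit_activation_series(attn_model, units, images, gain_map_attn)
    maps_b = sensitivity_maps(base_model, units, images, gain_map_base)
    maps_a = sensitivity_maps(attn_model, units, images, gain_map_attn)
    rows = []
    for ui, u in enumerate(units):
        rf_b = fit_rf_gaussian(maps_b[ui])
        rf_a = fit_rf_gaussian(maps_a[ui])
        m = rf_shift_metrics(rf_b, rf_a, locus)
        rows.append({
            "block": u.block, "channel": u.channel, "row": u.row, "col": u.col,
            "condition": condition,
            "base_r": rf_b.center[0], "base_c": rf_b.center[1],
            "attn_r": rf_a.center[0], "attn_c": rf_a.center[1],
            "fwhm_base": rf_b.fwhm, "fwhm_attn": rf_a.fwhm,
            "shift_toward_locus": m.shift_toward_locus,
            "shift_pct": m.shift_pct, "size_change": m.size_change,
            "shift_r": m.displacement[0], "shift_c": m.displacement[1],
            "eff_gain": effective_gain(act_b[ui], act_a[ui]),
            "valid": bool(rf_b.valid and rf_a.valid),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-position information maps
# ---------------------------------------------------------------------------

def delta_auc_map(observer: Observer, readouts: dict, stimulus_set,
                  gain_map=None, forward_fn=None, batch_size: int = 64
                  ) -> np.ndarray:
    """Change in per-position AUC (attention minus baseline) over the final
    feature map, averaged across categories.

    Each position's channel vector is projected on the target category's
    readout axis; the AUC of target-present vs target-absent scores measures
    that position's task information.
    """
    from .observer import auc, grids_as_batch

    images = grids_as_batch(stimulus_set.grids)
    fwd = forward_fn if forward_fn is not None else observer.forward

    def final_maps(gm):
        outs = []
        for start in range(0, len(images), batch_size):
            outs.append(fwd(images[start:start + batch_size], gain_map=gm).final_map)
        return np.concatenate(outs).astype(np.float64)

    fm_base = final_maps(None)
    fm_attn = final_maps(gain_map)
    h, w = fm_base.shape[1:3]
    cats = sorted({g.target_category for g in stimulus_set.grids})
    delta = np.zeros((h, w))
    for cat in cats:
        idx = [i for i, g in enumerate(stimulus_set.grids) if g.target_category == cat]
        present = [i for i in idx if stimulus_set.grids[i].target_present]
        absent = [i for i in idx if not stimulus_set.grids[i].target_present]
        coef = readouts[cat].coef
        for r in range(h):
            for c in range(w):
                s_b = fm_base[:, r, c, :] @ coef
                s_a = fm_attn[:, r, c, :] @ coef
                delta[r, c] += (auc(s_a[present], s_a[absent]) -
                                auc(s_b[present], s_b[absent]))
    return delta / len(cats)
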