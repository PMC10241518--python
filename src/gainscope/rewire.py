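"""Counterfactual model variants that reproduce the receptive-field effects
of Gaussian gain while nulling the gain itself.

Three variants, each operating on a copy of a trained observer:

* **Shift-only** — block-1 activations are resampled along a smoothed "shift
  map" derived from the RF displacements measured in the last block under
  Gaussian gain, so downstream units look at shifted image regions with no
  gain anywhere.
* **RF structure** — convolution kernels are reweighted tap-by-tap by the
  gain at each tap's image position, then rescaled so each kernel's L2 norm
  is exactly preserved; within-RF sensitivity shifts, overall gain does not.
* **Shrinkage** — the last block's 3x3 kernel taps are contracted toward
  their mean position by a distance-dependent shrinkage factor f_beta(d) and
  re-expressed on the integer grid by bilinear splitting, changing RF size
  while keeping position and gain fixed.

The structure and shrinkage variants require per-output-position kernels and
therefore replace the shared convolution with a locally connected layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .attention import GainField
from .network import BilinearResample, DTYPE, LocallyConnected2d
from .observer import Observer

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shift-only model
# ---------------------------------------------------------------------------

@dataclass
class ShiftMap:
    """Per-pixel RF displacement (px) at input resolution."""

    dr: np.ndarray
    dc: np.ndarray
    blur_sigma: float = 0.0

    @property
    def shape(self):
        return self.dr.shape


def build_shift_map(rf_centers, rf_shifts, image_shape, k: int = 20,
                    blur_sigma: float = 8.0, eps: float = 1.0) -> ShiftMap:
    """Interpolate sampled last-block RF shifts to a dense pixel map.

    For every pixel: take the ``k`` sampled units with the nearest baseline
    RF centers, average their (dr, dc) displacements with inverse-distance
    weights 1/(d + eps), then smooth each component with an isotropic
    Gaussian blur of ``blur_sigma`` px.
    """
    centers = np.asarray(rf_centers, float).reshape(-1, 2)
    shifts = np.asarray(rf_shifts, float).reshape(-1, 2)
    if centers.shape != shifts.shape:
        raise ValueError("rf_centers and rf_shifts must align")
    n = len(centers)
    if n < k:
        raise ValueError(f"need at least k={k} RF records, got {n}")
    H, W = image_shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1)           # (P, 2)
    d = np.linalg.norm(pix[:, None, :] - centers[None, :, :], axis=2)  # (P, n)
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    dn = np.take_along_axis(d, nearest, axis=1)
    w = 1.0 / (dn + eps)
    w /= w.sum(axis=1, keepdims=True)
    sh = shifts[nearest]                                        # (P, k, 2)
    mean_shift = (w[:, :, None] * sh).sum(axis=1)
    dr = mean_shift[:, 0].reshape(H, W)
    dc = mean_shift[:, 1].reshape(H, W)
    if blur_sigma > 0:
        dr = gaussian_filter(dr, blur_sigma)
        dc = gaussian_filter(dc, blur_sigma)
    return ShiftMap(dr, dc, blur_sigma)


def make_shift_only_observer(observer: Observer, shift_map: ShiftMap) -> Observer:
    """Observer copy whose block-1 output is resampled along the shift map.

    The activation at block-1 grid position q is replaced by the bilinear
    sample at q + shift(q) (shift converted from input pixels to block-1 grid
    units); samples beyond the border are clamped.  No gain map is applied
    anywhere, so the population-mean effective gain stays near 1.
    """
    if shift_map.shape != (observer.config.input_side,) * 2:
        raise ValueError("shift map must be at input resolution")
    variant = observer.copy()
    side0 = observer.config.block_sides()[0]
    scale = observer.config.input_side / side0
    q = np.arange(side0)
    centers = (q + 0.5) * scale - 0.5
    pix = np.clip(np.round(centers).astype(int), 0, observer.config.input_side - 1)
    dr = shift_map.dr[np.ix_(pix, pix)] / scale
    dc = shift_map.dc[np.ix_(pix, pix)] / scale
    src_rows = q[:, None] + dr
    src_cols = q[None, :] + dc
    variant.post_block_hooks = {0: BilinearResample(src_rows, src_cols)}
    return variant


def shift_only_forward(observer: Observer, images, shift_map: ShiftMap):
    """Convenience wrapper: one shift-only forward pass."""
    return make_shift_only_observer(observer, shift_map).forward(images)


# ---------------------------------------------------------------------------
# receptive-field structure model
# ---------------------------------------------------------------------------

def _conv_tap_image_coords(observer: Observer, block: int):
    """Image-space coordinates of every conv tap at ``block``.

    Returns (conv, S_out, coords, valid) where coords[i, u] is the image-space
    coordinate of tap offset u for output index i (same along rows/cols by
    symmetry) and valid[i, u] marks taps that read real input rather than
    zero padding.
    """
    conv = observer.blocks[block][0]
    if block == 0:
        in_side = observer.config.input_side
        t = 1.0
    else:
        in_side = observer.config.block_sides()[block - 1]
        t = observer.config.input_side / in_side
    s, p, k = conv.stride, conv.pad, conv.kh
    s_out = (in_side + 2 * p - k) // s + 1
    idx = np.arange(s_out)[:, None] * s + np.arange(k)[None, :] - p  # feature coords
    coords = (idx + 0.5) * t - 0.5                                   # image px
    valid = (idx >= 0) & (idx < in_side)
    return conv, s_out, coords, valid


def restructure_kernels(observer: Observer, field: GainField,
                        blocks: Optional[Sequence[int]] = None) -> Observer:
    """RF-structure variant: per output position, multiply each kernel tap by
    the Gaussian gain at that tap's image-space input position, then rescale
    the whole kernel so its L2 norm equals the original's exactly.

    A gain that is constant across a kernel's support therefore cancels, and
    beta = 1 leaves the model unchanged.  Zero-norm kernels are left as they
    are (and logged).  The result uses locally connected layers at the
    targeted blocks.
    """
    variant = observer.copy()
    blocks = list(blocks) if blocks is not None else list(range(len(observer.blocks)))
    for b in blocks:
        conv, s_out, coords, valid = _conv_tap_image_coords(variant, b)
        k = conv.kh
        # gain at every (output index, tap offset) pair
        rr = coords[:, :, None, None]            # (s_out, k, 1, 1) row coords
        cc = coords[None, None, :, :]            # (1, 1, s_out, k) col coords
        d2 = (rr - field.row) ** 2 + (cc - field.col) ** 2   # (s_out,k,s_out,k)
        g = ((field.beta - 1.0) * np.exp(-d2 / (2 * field.sigma**2)) + 1.0)
        g = g.transpose(0, 2, 1, 3)              # (i, j, u, v)
        # L2 norms over taps that read real input: border kernels must not
        # trade mass between padded and interior taps, or a net gain leaks in
        vmask = (valid[:, None, :, None] & valid[None, :, None, :]).astype(float)
        W = conv.W.astype(np.float64)            # (kh, kw, cin, cout)
        W2 = (W**2).sum(axis=2)                  # (kh, kw, cout)
        norm2 = np.einsum("ijuv,uvo->ijo", vmask, W2)
        gw = g[:, :, :, :, None, None] * W[None, None]   # (i,j,u,v,cin,cout)
        gw_norm2 = np.einsum("ijuv,ijuvo->ijo", vmask, (gw**2).sum(axis=4))
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(norm2 / gw_norm2)
        bad = ~np.isfinite(scale)
        if bad.any():
            # gw_norm2 = 0 with g > 0 implies the kernel is all zeros; a unit
            # scale leaves it unchanged, as required
            logger.info("restructure_kernels: %d zero-norm kernels left unchanged",
                        int(bad.sum()))
            scale = np.where(bad, 1.0, scale)
        W_lc = (gw * scale[:, :, None, None, None, :]).astype(DTYPE)
        variant.blocks[b][0] = LocallyConnected2d(
            W_lc, stride=conv.stride, pad=conv.pad,
            bias=None if conv.b is None else conv.b.copy())
    return variant


# ---------------------------------------------------------------------------
# shrinkage model
# ---------------------------------------------------------------------------

FULL_SCALE_SHRINK_REF = 112.0


def shrinkage_factor(d, beta: float, ref_scale: float = FULL_SCALE_SHRINK_REF):
    """Distance-dependent kernel contraction factor

        f_beta(d) = 1 - beta * exp(-2.44 d^2 / ref^2) * cos(2.89 d^2 / ref^2)

    modelled on the RF size-change profile observed under strong Gaussian
    gain; f = 1 means no change, f < 1 contraction near the locus, f > 1
    mild expansion at intermediate distances.
    """
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if not (0.0 <= beta < 1.0):
        raise ValueError("shrinkage beta must be in [0, 1)")
    u = d**2 / ref_scale**2
    return 1.0 - beta * np.exp(-2.44 * u) * np.cos(2.89 * u)


def shrink_rewire(observer: Observer, beta: float, locus,
                  ref_scale: Optional[float] = None) -> Observer:
    """Shrinkage variant acting on the last block's 3x3 convolution.

    Each output unit's tap positions x_i are moved to
    x'_i = f(d) * x_i + (1 - f(d)) * mean(x), with d the image-space distance
    from the unit to the locus; each virtual tap is split over its 4
    surrounding grid cells by bilinear weights (which sum to 1, conserving
    kernel mass per tap) and same-cell contributions are summed into a
    locally connected kernel.  Taps displaced outside the feature map fall in
    the zero-padding region.  f = 1 everywhere reproduces the original
    convolution exactly.
    """
    variant = observer.copy()
    b = len(variant.blocks) - 1
    conv, s_out, _, _ = _conv_tap_image_coords(variant, b)
    k, s, p = conv.kh, conv.stride, conv.pad
    if ref_scale is None:
        ref_scale = FULL_SCALE_SHRINK_REF * observer.config.input_side / 224.0
    margin = max(1, int(np.ceil((1.0 + beta) * (k - 1) / 2.0 - (k - 1) / 2.0)))
    kw_new = k + 2 * margin
    cin, cout = conv.W.shape[2], conv.W.shape[3]
    W_lc = np.zeros((s_out, s_out, kw_new, kw_new, cin, cout), DTYPE)
    # image-space centers of conv output units
    t = observer.config.input_side / s_out
    unit_centers = (np.arange(s_out) + 0.5) * t - 0.5
    offsets = np.arange(k, dtype=float)          # tap offsets within the kernel
    mean_off = offsets.mean()
    for i in range(s_out):
        for j in range(s_out):
            d = float(np.hypot(unit_centers[i] - locus[0],
                               unit_centers[j] - locus[1]))
            f = float(shrinkage_factor(d, beta, ref_scale))
            new_off = f * offsets + (1.0 - f) * mean_off     # per axis
            for u in range(k):
                r = new_off[u] + margin
                r0 = int(np.floor(r))
                fr = r - r0
                for v in range(k):
                    c = new_off[v] + margin
                    c0 = int(np.floor(c))
                    fc = c - c0
                    for (ri, wr) in ((r0, 1 - fr), (r0 + 1, fr)):
                        if wr == 0 or not (0 <= ri < kw_new):
                            continue
                        for (ci, wc) in ((c0, 1 - fc), (c0 + 1, fc)):
                            if wc == 0 or not (0 <= ci < kw_new):
                                continue
                            W_lc[i, j, ri, ci] += np.float32(wr * wc) * conv.W[u, v]
    variant.blocks[b][0] = LocallyConnected2d(
        W_lc, stride=s, pad=p + margin,
        bias=None if conv.b is None else conv.b.copy())
    return variant
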