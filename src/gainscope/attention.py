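"""Multiplicative attention fields and gain manipulations.

The central object is a Gaussian gain field applied to input pixels,

    g(r, c) = (beta - 1) * exp(-((r - r0)^2 + (c - c0)^2) / (2 sigma^2)) + 1,

peaking at ``beta`` over the cued location and decaying to 1.  Around it this
module provides: the flat-quadrant gain with quadrant-isolated forward passes
(the "gain-only" counterfactual), normalized exponentiation (a winner-take-
all-like nonlinearity that amplifies small gain differences), and the
propagated-gain map used to test whether gain at the output layer is
necessary and sufficient for the task benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import DTYPE
from .observer import LayerActivations, Observer, UnitRef
from .stimuli import QUADRANTS

logger = logging.getLogger(__name__)

FULL_SCALE_SIGMA_PX = 56.0   # at 224-px composites (about 2.5 degrees)
FULL_SCALE_SIDE = 224


@dataclass(frozen=True)
class GainField:
    """Parametric attention field: center (row, col), width sigma (px), and
    peak multiplicative strength beta (dimensionless, >= 1)."""

    row: float
    col: float
    sigma: float
    beta: float

    def __post_init__(self):
        if self.beta < 1.0:
            raise ValueError("suppressive fields (beta < 1) are out of scope")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def quadrant_center(image_side: int, quadrant: str = "NW") -> tuple:
    """Center of a quadrant in 0-based pixel-center coordinates:
    (B/2 - 0.5, B/2 - 0.5) within the quadrant, B = image_side / 2."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    B = image_side // 2
    base = (B - 1) / 2.0
    dr = 0 if quadrant in ("NW", "NE") else B
    dc = 0 if quadrant in ("NW", "SW") else B
    return (base + dr, base + dc)


def default_sigma(image_side: int) -> float:
    """Full-scale sigma = 56 px; scaled with the composite side."""
    return FULL_SCALE_SIGMA_PX * image_side / FULL_SCALE_SIDE


def field_for_quadrant(image_side: int, quadrant: str = "NW", beta: float = 4.0,
                       sigma: Optional[float] = None) -> GainField:
    r0, c0 = quadrant_center(image_side, quadrant)
    return GainField(r0, c0, sigma if sigma is not None else default_sigma(image_side),
                     beta)


def gaussian_gain_map(field: GainField, shape) -> np.ndarray:
    """Rasterize the Gaussian gain field to a (rows, cols) multiplicative map."""
    H, W = shape
    if H <= 0 or W <= 0:
        raise ValueError("shape must be positive")
    r = np.arange(H, dtype=np.float64)[:, None]
    c = np.arange(W, dtype=np.float64)[None, :]
    d2 = (r - field.row) ** 2 + (c - field.col) ** 2
    return (field.beta - 1.0) * np.exp(-d2 / (2.0 * field.sigma**2)) + 1.0


def flat_quadrant_gain(field: GainField, quadrant: str, shape) -> np.ndarray:
    """Constant gain inside one quadrant equal to the spatial mean of the
    Gaussian gain over that quadrant; 1 elsewhere."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    H, W = shape
    gmap = gaussian_gain_map(field, shape)
    B_r, B_c = H // 2, W // 2
    rs = slice(0, B_r) if quadrant in ("NW", "NE") else slice(B_r, H)
    cs = slice(0, B_c) if quadrant in ("NW", "SW") else slice(B_c, W)
    flat = np.ones((H, W), np.float64)
    flat[rs, cs] = gmap[rs, cs].mean()
    return flat


# ---------------------------------------------------------------------------
# quadrant-isolated forward (the gain-only model's plumbing)
# ---------------------------------------------------------------------------

class QuadrantIsolatedObserver:
    """Forward pass in which each image quadrant is processed independently
    (zero padding at quadrant borders) and the per-quadrant feature maps are
    stitched back together, so no unit's activation depends on pixels outside
    its own quadrant.

    At desk scale the stitched maps have exactly the geometry of the plain
    forward pass (a 32-px quadrant yields a 1x1 final map; four of them tile
    the plain model's 2x2), so the same pooled readouts apply.
    """

    def __init__(self, observer: Observer):
        self.observer = observer
        self.config = observer.config
        if observer.config.input_side % 2:
            raise ValueError("quadrant isolation requires an even image side")

    def _quadrant_views(self, x):
        B = x.shape[1] // 2
        return {
            "NW": x[:, :B, :B], "NE": x[:, :B, B:],
            "SW": x[:, B:, :B], "SE": x[:, B:, B:],
        }

    def _run_blocks(self, x):
        outs = []
        for block in self.observer.blocks:
            for layer in block:
                x = layer.forward(x)
            outs.append(x)
        return outs

    def forward(self, images, gain_map=None) -> LayerActivations:
        x = np.asarray(images, DTYPE)
        if x.ndim == 3:
            x = x[None]
        if gain_map is not None:
            x = x * np.asarray(gain_map, DTYPE)[None, :, :, None]
        per_quadrant = {q: self._run_blocks(v) for q, v in
                        self._quadrant_views(x).items()}
        stitched = []
        n_blocks = len(self.observer.blocks)
        for bi in range(n_blocks):
            qmaps = {q: per_quadrant[q][bi] for q in QUADRANTS}
            h, w = qmaps["NW"].shape[1:3]
            full = np.zeros((x.shape[0], 2 * h, 2 * w, qmaps["NW"].shape[3]), DTYPE)
            full[:, :h, :w] = qmaps["NW"]
            full[:, :h, w:] = qmaps["NE"]
            full[:, h:, :w] = qmaps["SW"]
            full[:, h:, w:] = qmaps["SE"]
            stitched.append(full)
        return LayerActivations(stitched)

    def unit_gradient(self, images, unit: UnitRef, gain_map=None) -> np.ndarray:
        """Input-pixel gradient of one stitched-map unit; nonzero only inside
        the unit's own quadrant (the isolation contract)."""
        x = np.asarray(images, DTYPE)
        if x.ndim == 3:
            x = x[None]
        side = x.shape[1]
        gm = None if gain_map is None else np.asarray(gain_map, DTYPE)
        xg = x if gm is None else x * gm[None, :, :, None]
        # locate the unit's quadrant in the stitched block-`unit.block` map
        qside = None
        test = self._run_blocks(self._quadrant_views(xg)["NW"][:1])
        qside = test[unit.block].shape[1]
        row_q, col_q = unit.row // qside, unit.col // qside
        quadrant = {(0, 0): "NW", (0, 1): "NE", (1, 0): "SW", (1, 1): "SE"}[
            (row_q, col_q)]
        local = UnitRef(unit.block, unit.channel,
                        unit.row - row_q * qside, unit.col - col_q * qside)
        xq = self._quadrant_views(xg)[quadrant]
        outs = self._run_blocks(xq)
        dy = np.zeros_like(outs[unit.block])
        dy[:, local.row, local.col, local.channel] = 1.0
        for bi in range(unit.block, -1, -1):
            for layer in reversed(self.observer.blocks[bi]):
                dy = layer.backward(dy)
        grad = np.zeros_like(x)
        B = side // 2
        rs = slice(0, B) if quadrant in ("NW", "NE") else slice(B, side)
        cs = slice(0, B) if quadrant in ("NW", "SW") else slice(B, side)
        grad[:, rs, cs] = dy
        if gm is not None:
            grad *= gm[None, :, :, None]
        return grad


def quadrant_isolated_forward(observer: Observer, images, gain_map=None
                              ) -> LayerActivations:
    return QuadrantIsolatedObserver(observer).forward(images, gain_map=gain_map)


# ---------------------------------------------------------------------------
# normalized exponentiation
# ---------------------------------------------------------------------------

def normalized_exponentiation(feature_map: np.ndarray, xi: float) -> np.ndarray:
    """Winner-take-all-like amplification: raise activations to exponent xi
    and rescale so the map's L1 mass is conserved,

        b = (sum|a| / sum|a|^xi) * a^xi.

    Sums run over all positions and channels (per image if a batch axis is
    present).  An all-zero map is returned unchanged (the normalizer is
    undefined in that limit); xi = 1 is the identity.
    """
    if xi < 1.0:
        raise ValueError("exponent xi must be >= 1")
    a = np.asarray(feature_map)
    batched = a.ndim == 4
    ab = a if batched else a[None]
    absa = np.abs(ab)
    mass = absa.sum(axis=(1, 2, 3))
    powa = absa ** xi
    mass_pow = powa.sum(axis=(1, 2, 3))
    scale = np.ones_like(mass)
    ok = mass_pow > 0
    scale[ok] = mass[ok] / mass_pow[ok]
    if not ok.all():
        logger.info("normalized_exponentiation: %d all-zero maps left unchanged",
                    int((~ok).sum()))
    out = np.where(ok[:, None, None, None],
                   scale[:, None, None, None] * np.sign(ab) * powa, ab)
    out = out.astype(ab.dtype)
    return out if batched else out[0]


class NormalizedExponentiation:
    """Forward-only block hook applying normalized exponentiation."""

    def __init__(self, xi: float):
        self.xi = float(xi)

    def forward(self, x):
        return normalized_exponentiation(x, self.xi)


def _block0_unit_geometry(observer: Observer):
    """Analytic geometry of first-block units: input-pixel support center per
    spatial position and the support-based FWHM (conv k, stride s, pad p,
    then 2x2 pool).  Exact for the architecture; used to classify units as
    fully inside/outside a gain field."""
    cfg = observer.config
    k, s, p = cfg.kernel_sizes[0], cfg.strides[0], cfg.kernel_sizes[0] // 2
    side = cfg.block_sides()[0]
    pos = np.arange(side)
    # pool position q covers conv outputs 2q and 2q+1; conv t reads
    # [s*t - p, s*t - p + k - 1]
    lo = s * (2 * pos) - p
    hi = s * (2 * pos + 1) - p + k - 1
    centers = (lo + hi) / 2.0
    width = float(hi[0] - lo[0] + 1)
    fwhm = width / 2.0   # half-max width of the tent-like support profile
    rr, cc = np.meshgrid(centers, centers, indexing="ij")
    return np.stack([rr, cc], axis=-1), fwhm


def exponent_amplification(observer: Observer, field: GainField, xi: float,
                           images, eps: float = 1e-7) -> float:
    """Ratio of mean effective gain of first-block units fully inside the
    gain field to that of units fully outside, with normalized exponentiation
    (exponent xi) applied at the first block's output.

    A unit is "fully inside" when its support center sits 2 FWHM inside the
    field's 2-sigma disc, "fully outside" when 2 FWHM beyond it.  Effective
    gain is the per-unit std ratio of activations across the stimulus batch,
    with versus without the input gain (exponentiation active in both).
    """
    images = np.asarray(images, DTYPE)
    centers, fwhm = _block0_unit_geometry(observer)
    d = np.hypot(centers[..., 0] - field.row, centers[..., 1] - field.col)
    inside = d + 2 * fwhm <= 2 * field.sigma
    outside = d - 2 * fwhm >= 2 * field.sigma
    if not inside.any() or not outside.any():
        raise ValueError("no first-block units fully inside or outside the field")
    hook = {0: NormalizedExponentiation(xi)}
    gmap = gaussian_gain_map(field, (observer.config.input_side,) * 2)
    base = observer.forward(images, post_block_hooks=hook).block_outputs[0]
    attn = observer.forward(images, gain_map=gmap,
                            post_block_hooks=hook).block_outputs[0]
    std_b = base.std(axis=0)
    std_a = attn.std(axis=0)
    valid = std_b > eps
    ratio = np.full(std_b.shape, np.nan)
    ratio[valid] = std_a[valid] / std_b[valid]
    gain_in = np.nanmean(ratio[inside])
    gain_out = np.nanmean(ratio[outside])
    if not np.isfinite(gain_in) or not np.isfinite(gain_out) or gain_out == 0:
        raise ValueError("degenerate activations: cannot form amplification ratio")
    return float(gain_in / gain_out)


# ---------------------------------------------------------------------------
# propagated gain
# ---------------------------------------------------------------------------

def propagated_gain_map(observer: Observer, gain_map, images,
                        batch_size: int = 64, rel_eps: float = 1e-3) -> np.ndarray:
    """Average effective gain at each final-layer spatial position.

    Runs the stimuli with and without the input gain and takes, per position
    and channel, the ratio of activation standard deviations across stimuli.
    Channels whose baseline variance is negligible (std below ``rel_eps``
    times the map's median channel std) have no meaningful ratio and are
    excluded from the channel average; a position with no valid channel is
    set to 1 and logged.
    """
    images = np.asarray(images, DTYPE)
    if len(images) == 0:
        raise ValueError("propagated gain map needs a non-empty stimulus sample")
    finals_b, finals_a = [], []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        finals_b.append(observer.forward(batch).final_map)
        finals_a.append(observer.forward(batch, gain_map=gain_map).final_map)
    base = np.concatenate(finals_b).astype(np.float64)
    attn = np.concatenate(finals_a).astype(np.float64)
    std_b = base.std(axis=0)
    std_a = attn.std(axis=0)
    scale = np.median(std_b[std_b > 0]) if np.any(std_b > 0) else 0.0
    valid = std_b > rel_eps * scale
    ratio = np.where(valid, std_a / np.where(valid, std_b, 1.0), np.nan)
    with np.errstate(invalid="ignore"):
        gmap = np.nanmean(ratio, axis=-1)
    bad = ~np.isfinite(gmap)
    if bad.any():
        logger.warning("propagated_gain_map: %d positions had zero-variance "
                       "baselines; set to 1", int(bad.sum()))
        gmap[bad] = 1.0
    return gmap


def apply_output_gain(final_map: np.ndarray, gain_map: np.ndarray,
                      mode: str = "multiply") -> np.ndarray:
    """Elementwise multiply/divide of a final feature map by a per-position
    gain map, broadcast over channels."""
    fm = np.asarray(final_map)
    gm = np.asarray(gain_map, np.float64)
    if gm.shape != fm.shape[-3:-1]:
        raise ValueError(f"gain map {gm.shape} does not match final map spatial "
                         f"shape {fm.shape[-3:-1]}")
    if mode == "multiply":
        return (fm * gm[..., None]).astype(fm.dtype)
    if mode == "divide":
        if np.any(gm == 0):
            raise ValueError("cannot divide by a gain map with zero entries")
        return (fm / gm[..., None]).astype(fm.dtype)
    raise ValueError(f"mode must be 'multiply' or 'divide', got {mode!r}")
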