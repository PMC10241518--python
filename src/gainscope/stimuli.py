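"""Synthetic stimulus generation: category image libraries, 2x2 composite
grids for detection and discrimination, and pixel-scramble masks.

The stimuli emulate a cued object-detection protocol in which four square
base images are tiled into one "composite grid" and an observer reports the
presence of a target category.  Because no external image set is consumed,
categories are parametric texture/shape families — oriented gratings
modulated by a shape mask with a category color tint plus pixel noise —
chosen to be discriminable by a small CNN trained on a desktop CPU.

Geometry: the full-scale composite spans 224 px over 10 degrees of visual
angle (22.4 px/deg); base images are composite_side/2 on a side.  All
coordinates are 0-based, row-major ``(row, col)``; the NW quadrant is rows
and cols ``[0, B)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

QUADRANTS = ("NW", "NE", "SW", "SE")

FULL_SCALE_COMPOSITE_SIDE = 224
FULL_SCALE_EXTENT_DEG = 10.0


class ResourceExhaustedError(RuntimeError):
    """Raised when a library has too few images for the requested protocol."""


def pixels_per_degree(composite_side: int = FULL_SCALE_COMPOSITE_SIDE,
                      extent_deg: float = FULL_SCALE_EXTENT_DEG) -> float:
    """Stimulus resolution: composite side in px over its angular extent."""
    return composite_side / extent_deg


# ---------------------------------------------------------------------------
# category specifications and base-image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategorySpec:
    """Parametric texture family standing in for one object category."""

    category_id: int
    orientation: float          # grating orientation, degrees
    spatial_freq: float         # cycles per image
    shape_family: int           # 0 disk, 1 square, 2 annulus, 3 cross
    contrast: float             # in [0, 1]
    color: tuple = (1.0, 1.0, 1.0)  # per-channel tint
    noise_sd: float = 0.6       # additive pixel noise, image units


_COLOR_WHEEL = [
    (1.00, 0.55, 0.55), (0.55, 1.00, 0.55), (0.55, 0.55, 1.00),
    (1.00, 1.00, 0.50), (1.00, 0.55, 1.00), (0.55, 1.00, 1.00),
    (1.00, 0.80, 0.55), (0.75, 0.75, 0.75),
]


def default_category_specs(n_categories: int, seed: int = 0,
                           noise_sd: float = 0.6, contrast: float = 0.65,
                           color_mix: float = 0.45) -> list[CategorySpec]:
    """Evenly spread orientations/frequencies so all pairs are separable.

    The default contrast/noise/tint levels put a trained desk observer in the
    mid-range operating regime of the detection task (single-image readout
    validation AUC around 0.9, composite distributed AUC around 0.7) rather
    than at ceiling; ``color_mix`` blends the category tint toward neutral so
    color is a weak cue rather than a giveaway.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    freqs = rng.permutation(np.linspace(3.0, 9.0, n_categories))
    specs = []
    for k in range(n_categories):
        tint = np.asarray(_COLOR_WHEEL[k % len(_COLOR_WHEEL)])
        color = tuple(float(v) for v in (1.0 - color_mix) + color_mix * tint)
        specs.append(CategorySpec(
            category_id=k,
            orientation=180.0 * k / n_categories,
            spatial_freq=float(freqs[k]),
            shape_family=k % 4,
            contrast=contrast,
            color=color,
            noise_sd=noise_sd,
        ))
    return specs


def _shape_mask(family: int, side: int, jitter_rc, rng) -> np.ndarray:
    r = np.arange(side)[:, None] - (side - 1) / 2 - jitter_rc[0]
    c = np.arange(side)[None, :] - (side - 1) / 2 - jitter_rc[1]
    rad = side * 0.35
    if family % 4 == 0:        # disk
        return (r**2 + c**2 <= rad**2).astype(np.float32)
    if family % 4 == 1:        # square
        return ((np.abs(r) <= rad) & (np.abs(c) <= rad)).astype(np.float32)
    if family % 4 == 2:        # annulus
        d2 = r**2 + c**2
        return ((d2 <= rad**2) & (d2 >= (0.45 * rad) ** 2)).astype(np.float32)
    # cross
    return ((np.abs(r) <= 0.4 * rad) | (np.abs(c) <= 0.4 * rad)).astype(np.float32) * \
        ((np.abs(r) <= rad) & (np.abs(c) <= rad))


def render_base_image(spec: CategorySpec, image_side: int, rng) -> np.ndarray:
    """One (side, side, 3) float32 image in [0, 1] from a category spec.

    Within-category variability: random grating phase, small orientation and
    position jitter, and independent additive Gaussian pixel noise.
    """
    side = int(image_side)
    theta = np.deg2rad(spec.orientation + rng.normal(0.0, 4.0))
    phase = rng.uniform(0.0, 2 * np.pi)
    jitter = rng.normal(0.0, side * 0.04, size=2)
    r = np.arange(side)[:, None] / side
    c = np.arange(side)[None, :] / side
    grating = np.sin(2 * np.pi * spec.spatial_freq *
                     (c * np.cos(theta) + r * np.sin(theta)) + phase)
    mask = _shape_mask(spec.shape_family, side, jitter, rng)
    pattern = 0.5 + 0.5 * spec.contrast * grating * (0.35 + 0.65 * mask)
    img = pattern[:, :, None] * np.asarray(spec.color, np.float32)[None, None, :]
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


@dataclass
class BaseImage:
    pixels: np.ndarray          # (B, B, 3) in [0, 1]
    category_id: int
    image_id: int


@dataclass
class Library:
    """A generated category library with per-category image indices."""

    images: list
    image_side: int
    specs: list
    seed: int

    @property
    def n_categories(self):
        return len(self.specs)

    def category_ids(self):
        return [s.category_id for s in self.specs]

    def by_category(self, category_id) -> list:
        return [im for im in self.images if im.category_id == category_id]

    def subset(self, image_ids) -> "Library":
        keep = set(image_ids)
        return Library([im for im in self.images if im.image_id in keep],
                       self.image_side, self.specs, self.seed)

    def split(self, fractions: Sequence[float], seed: int = 0):
        """Per-category disjoint splits (observer-train / readout / eval)."""
        rng = np.random.default_rng(seed)
        parts = [[] for _ in fractions]
        for cat in self.category_ids():
            imgs = self.by_category(cat)
            order = rng.permutation(len(imgs))
            bounds = np.cumsum([int(round(f * len(imgs))) for f in fractions])
            start = 0
            for pi, stop in enumerate(bounds):
                parts[pi].extend(imgs[i] for i in order[start:stop])
                start = stop
        return [Library(p, self.image_side, self.specs, self.seed) for p in parts]


def generate_category_library(n_categories: int, n_images_per_category: int,
                              image_side: int, seed: int = 0,
                              specs: Optional[list] = None,
                              noise_sd: float = 0.6) -> Library:
    """Generate ``n_categories x n_images_per_category`` base images.

    Output is a pure function of ``(specs, seed)``: each image's RNG is keyed
    by (seed, category, index), so the same call regenerates bit-identical
    pixels regardless of generation order.
    """
    if n_categories < 2 or n_images_per_category < 1:
        raise ValueError("n_categories must be >= 2 and counts positive")
    if image_side < 16:
        raise ValueError("image_side must be >= 16")
    if specs is None:
        specs = default_category_specs(n_categories, seed=seed, noise_sd=noise_sd)
    images = []
    image_id = 0
    for spec in specs:
        for i in range(n_images_per_category):
            rng = np.random.default_rng([seed, spec.category_id, i])
            images.append(BaseImage(render_base_image(spec, image_side, rng),
                                    spec.category_id, image_id))
            image_id += 1
    return Library(images, int(image_side), list(specs), seed)


# ---------------------------------------------------------------------------
# composite grids
# ---------------------------------------------------------------------------

@dataclass
class CompositeGrid:
    pixels: np.ndarray                  # (2B, 2B, 3)
    quadrant_categories: tuple          # (NW, NE, SW, SE) category ids
    target_present: bool
    target_quadrant: Optional[str]      # in QUADRANTS, or None
    target_category: int                # category the readout looks for
    source_image_ids: tuple             # (NW, NE, SW, SE) image ids
    grid_id: int = -1


def _quadrant_slices(B: int) -> dict:
    return {
        "NW": (slice(0, B), slice(0, B)),
        "NE": (slice(0, B), slice(B, 2 * B)),
        "SW": (slice(B, 2 * B), slice(0, B)),
        "SE": (slice(B, 2 * B), slice(B, 2 * B)),
    }


def assemble_grid(quadrant_images: dict) -> np.ndarray:
    """Tile four base images (dict keyed by quadrant) into one composite."""
    B = quadrant_images["NW"].pixels.shape[0]
    pixels = np.empty((2 * B, 2 * B, 3), np.float32)
    for q, (rs, cs) in _quadrant_slices(B).items():
        pixels[rs, cs] = quadrant_images[q].pixels
    return pixels


def extract_quadrant(pixels: np.ndarray, quadrant: str) -> np.ndarray:
    B = pixels.shape[0] // 2
    rs, cs = _quadrant_slices(B)[quadrant]
    return pixels[rs, cs]


@dataclass
class StimulusSet:
    grids: list
    protocol: str

    def manifest(self) -> pd.DataFrame:
        rows = []
        for g in self.grids:
            rows.append({
                "grid_id": g.grid_id,
                "protocol": self.protocol,
                "target_category": g.target_category,
                "target_present": g.target_present,
                "target_quadrant": g.target_quadrant or "",
                **{f"q_{q}": g.quadrant_categories[i] for i, q in enumerate(QUADRANTS)},
                **{f"src_{q}": g.source_image_ids[i] for i, q in enumerate(QUADRANTS)},
            })
        return pd.DataFrame(rows)

    def save(self, directory):
        """Write PNGs plus a CSV manifest."""
        from pathlib import Path

        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for g in self.grids:
            arr = (np.clip(g.pixels, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / f"grid_{g.grid_id:05d}.png")
        self.manifest().to_csv(directory / "manifest.csv", index=False)


def _sample_images(pool: list, n: int, rng, replace_ok: bool):
    if len(pool) >= n:
        idx = rng.choice(len(pool), size=n, replace=False)
    elif replace_ok:
        idx = rng.choice(len(pool), size=n, replace=True)
    else:
        raise ResourceExhaustedError(
            f"need {n} images but pool has {len(pool)} (short by {n - len(pool)})")
    return [pool[i] for i in idx]


def build_detection_composites(library: Library, protocol: str = "model",
                               seed: int = 0, n_present: int = 64,
                               n_absent: int = 64,
                               categories: Optional[Sequence[int]] = None
                               ) -> StimulusSet:
    """Detection composites for every target category.

    ``protocol="human"``: per category exactly 80 grids — 40 target-present
    with targets placed 10 times in each corner, 40 target-absent — with all
    four quadrant categories distinct and distractors drawn from non-target
    categories.  ``protocol="model"``: target always in the NW corner
    (translation invariance makes corner choice immaterial for the model) and
    the present/absent counts are configurable.
    """
    if protocol not in ("human", "model"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if library.n_categories < 5:
        raise ResourceExhaustedError(
            "detection grids need 4 distinct distractor categories, so the "
            "library must have at least 5 categories")
    cats = list(categories) if categories is not None else library.category_ids()
    rng = np.random.default_rng([seed, 1])
    if protocol == "human":
        n_present, n_absent = 40, 40
    grids = []
    grid_id = 0
    for target_cat in cats:
        other_cats = [c for c in library.category_ids() if c != target_cat]
        target_pool = library.by_category(target_cat)
        targets = _sample_images(target_pool, n_present, rng,
                                 replace_ok=(protocol == "model"))
        if protocol == "human":
            corners = [q for q in QUADRANTS for _ in range(n_present // 4)]
        else:
            corners = ["NW"] * n_present
        for ti, (timg, corner) in enumerate(zip(targets, corners)):
            dcats = rng.choice(other_cats, size=3, replace=False)
            quadrant_imgs = {}
            qi = iter(dcats)
            for q in QUADRANTS:
                if q == corner:
                    quadrant_imgs[q] = timg
                else:
                    pool = library.by_category(int(next(qi)))
                    quadrant_imgs[q] = pool[rng.integers(len(pool))]
            grids.append(_make_grid(quadrant_imgs, corner, target_cat, grid_id))
            grid_id += 1
        for ai in range(n_absent):
            dcats = rng.choice(other_cats, size=4, replace=False)
            quadrant_imgs = {}
            for q, dc in zip(QUADRANTS, dcats):
                pool = library.by_category(int(dc))
                quadrant_imgs[q] = pool[rng.integers(len(pool))]
            grids.append(_make_grid(quadrant_imgs, None, target_cat, grid_id))
            grid_id += 1
    return StimulusSet(grids, protocol)


def _make_grid(quadrant_imgs, target_quadrant, target_cat, grid_id):
    return CompositeGrid(
        pixels=assemble_grid(quadrant_imgs),
        quadrant_categories=tuple(quadrant_imgs[q].category_id for q in QUADRANTS),
        target_present=target_quadrant is not None,
        target_quadrant=target_quadrant,
        target_category=target_cat,
        source_image_ids=tuple(quadrant_imgs[q].image_id for q in QUADRANTS),
        grid_id=grid_id,
    )


@dataclass
class DiscriminationPair:
    grid_a: CompositeGrid
    grid_b: CompositeGrid
    category_a: int
    category_b: int


def build_discrimination_pairs(library: Library, category_pairs: Sequence[tuple],
                               seed: int = 0, n_pairs: int = 450) -> list:
    """Discrimination composite pairs.

    Per (A, B) category pair, ``n_pairs`` pairs of composites: one with an A
    image at NW and one with a B image at NW; the other three quadrants are
    filled independently from A or B with probability 0.5.  Target images are
    unique across the pair-set's composites (they may recur as distractors).
    """
    rng = np.random.default_rng([seed, 2])
    out = []
    grid_id = 0
    for (cat_a, cat_b) in category_pairs:
        if cat_a == cat_b:
            raise ValueError("discrimination pair must use two distinct categories")
        pools = {cat_a: library.by_category(cat_a), cat_b: library.by_category(cat_b)}
        for cat in (cat_a, cat_b):
            if len(pools[cat]) < n_pairs:
                raise ResourceExhaustedError(
                    f"category {cat} has {len(pools[cat])} images; {n_pairs} unique "
                    f"targets requested (short by {n_pairs - len(pools[cat])})")
        targets_a = _sample_images(pools[cat_a], n_pairs, rng, replace_ok=False)
        targets_b = _sample_images(pools[cat_b], n_pairs, rng, replace_ok=False)
        for ta, tb in zip(targets_a, targets_b):
            pair_grids = []
            for timg, tcat in ((ta, cat_a), (tb, cat_b)):
                quadrant_imgs = {"NW": timg}
                for q in QUADRANTS[1:]:
                    dc = cat_a if rng.random() < 0.5 else cat_b
                    pool = pools[dc]
                    quadrant_imgs[q] = pool[rng.integers(len(pool))]
                pair_grids.append(_make_grid(quadrant_imgs, "NW", tcat, grid_id))
                grid_id += 1
            out.append(DiscriminationPair(pair_grids[0], pair_grids[1], cat_a, cat_b))
    return out


def scramble_mask(grid, seed: int = 0) -> np.ndarray:
    """Luminance-matched mask: a seed-deterministic permutation of the
    composite's pixel locations (RGB triplets move together)."""
    pixels = grid.pixels if isinstance(grid, CompositeGrid) else np.asarray(grid)
    H, W, C = pixels.shape
    rng = np.random.default_rng([seed, 3])
    perm = rng.permutation(H * W)
    return pixels.reshape(H * W, C)[perm].reshape(H, W, C)
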