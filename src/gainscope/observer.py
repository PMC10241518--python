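"""The convolutional observer model and its task readouts.

The observer is a four-block feedforward CNN patterned on CORnet-Z, a
network whose blocks map onto primate V1/V2/V4/IT: each block is a
convolution (stride 2 in the first block), a ReLU, and a 2x2 stride-2 max
pool.  At full scale (224x224x3 input, 64/128/256/512 channels) the block
outputs are 56x56, 28x28, 14x14 and 7x7.  Both the spatial side and the
channel widths are configurable: the experiment pipeline keeps the full
224-px geometry with narrow (16/32/64/128) channels, while unit tests use
small 32/64-px configurations.

The encoding of an image is the spatial average of the last block's feature
map.  Per-category task readouts are linear classifiers (logistic regression
with L2 regularization) over that encoding, trained on single full-size base
images and evaluated on composite grids — mirroring a protocol in which the
classifier has only ever seen the target category filling the image, so a
composite (target in one quadrant) yields diluted evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .network import Adam, Conv2d, DTYPE, Linear, MaxPool2x2, ReLU, softmax_cross_entropy
from .stimuli import CompositeGrid, Library


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverConfig:
    input_side: int = 64
    channels: tuple = (16, 32, 64, 128)
    kernel_sizes: tuple = (7, 3, 3, 3)
    strides: tuple = (2, 1, 1, 1)
    use_bias: bool = True
    n_categories: int = 8
    seed: int = 0

    @classmethod
    def full_scale(cls, n_categories: int = 20, **kw) -> "ObserverConfig":
        """The full CORnet-Z architecture: 224 input, 64/128/256/512 channels."""
        return cls(input_side=224, channels=(64, 128, 256, 512),
                   n_categories=n_categories, **kw)

    @classmethod
    def desk(cls, **kw) -> "ObserverConfig":
        return cls(**kw)

    def block_sides(self) -> list:
        side = self.input_side
        out = []
        for s in self.strides:
            side = side // s // 2   # conv stride, then 2x2 pool
            out.append(side)
        return out


@dataclass(frozen=True)
class UnitRef:
    """One unit in a block's post-pool output, (block, channel, row, col)."""
    block: int
    channel: int
    row: int
    col: int


@dataclass
class LayerActivations:
    """Post-pool feature maps per block plus the pooled encoding."""

    block_outputs: list

    @property
    def final_map(self) -> np.ndarray:
        return self.block_outputs[-1]

    @property
    def encoding(self) -> np.ndarray:
        return self.final_map.mean(axis=(1, 2))


class Observer:
    """Feedforward convolutional observer with gradient access.

    ``forward`` optionally applies a multiplicative per-pixel gain map to the
    input (the attention manipulation) and per-block output transforms
    (``post_block_hooks``), e.g. normalized exponentiation or the shift-only
    resampling.  ``unit_gradient`` backpropagates from a single post-pool
    unit to the input pixels, which is how receptive fields are estimated.
    """

    def __init__(self, config: ObserverConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks = []
        c_in = 3
        for k, s, c_out in zip(config.kernel_sizes, config.strides, config.channels):
            conv = Conv2d(k, k, c_in, c_out, stride=s, pad=k // 2,
                          bias=config.use_bias, rng=rng)
            self.blocks.append([conv, ReLU(), MaxPool2x2()])
            c_in = c_out
        self.head = Linear(config.channels[-1], config.n_categories, rng=rng)
        # persistent per-block output transforms (used by model variants)
        self.post_block_hooks: dict = {}

    # -- forward / backward --------------------------------------------------

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, DTYPE)
        if images.ndim == 3:
            images = images[None]
        if images.shape[1] != self.config.input_side or \
                images.shape[2] != self.config.input_side or images.shape[3] != 3:
            raise ValueError(
                f"expected (n, {self.config.input_side}, {self.config.input_side}, 3) "
                f"input, got {images.shape}")
        return images

    def forward(self, images, gain_map=None,
                post_block_hooks=None) -> LayerActivations:
        x = self._check_input(images)
        if gain_map is not None:
            gain_map = np.asarray(gain_map, DTYPE)
            if gain_map.shape != x.shape[1:3]:
                raise ValueError(
                    f"gain map shape {gain_map.shape} does not match image "
                    f"side {x.shape[1:3]}")
            x = x * gain_map[None, :, :, None]
        hooks = dict(self.post_block_hooks)
        if post_block_hooks:
            hooks.update(post_block_hooks)
        outputs = []
        for bi, block in enumerate(self.blocks):
            for layer in block:
                x = layer.forward(x)
            hook = hooks.get(bi)
            if hook is not None:
                x = hook.forward(x) if hasattr(hook, "forward") else hook(x)
            outputs.append(x)
        self._hooks_used = hooks
        self._gain_map = gain_map
        return LayerActivations(outputs)

    def encode(self, images, gain_map=None, post_block_hooks=None) -> np.ndarray:
        return self.forward(images, gain_map, post_block_hooks).encoding

    def unit_gradient(self, images, unit: UnitRef, gain_map=None,
                      post_block_hooks=None) -> np.ndarray:
        """d(activation of `unit`) / d(input pixels), per image: (n, H, W, 3).

        The gradient is taken with respect to the *original* pixels, i.e. it
        chains through any applied gain map (this is what makes receptive
        fields measured under attention shift toward the locus).
        """
        acts = self.forward(images, gain_map, post_block_hooks)
        out = acts.block_outputs[unit.block]
        n = out.shape[0]
        dy = np.zeros_like(out)
        dy[:, unit.row, unit.col, unit.channel] = 1.0
        for bi in range(unit.block, -1, -1):
            hook = self._hooks_used.get(bi)
            if hook is not None:
                if not hasattr(hook, "backward"):
                    raise ValueError(
                        f"block-{bi} hook {type(hook).__name__} does not support "
                        "gradient backpropagation")
                dy = hook.backward(dy)
            for layer in reversed(self.blocks[bi]):
                dy = layer.backward(dy)
        if self._gain_map is not None:
            dy = dy * self._gain_map[None, :, :, None]
        return dy

    def unit_gradients(self, images, units, gain_map=None,
                       post_block_hooks=None) -> list:
        """Input-pixel gradients for many units from a single forward pass
        (layer caches are read-only during backward, so backpropagation can
        be repeated per unit); much faster than per-unit ``unit_gradient``."""
        acts = self.forward(images, gain_map, post_block_hooks)
        grads = []
        for unit in units:
            out = acts.block_outputs[unit.block]
            dy = np.zeros_like(out)
            dy[:, unit.row, unit.col, unit.channel] = 1.0
            for bi in range(unit.block, -1, -1):
                hook = self._hooks_used.get(bi)
                if hook is not None:
                    if not hasattr(hook, "backward"):
                        raise ValueError(
                            f"block-{bi} hook {type(hook).__name__} does not "
                            "support gradient backpropagation")
                    dy = hook.backward(dy)
                for layer in reversed(self.blocks[bi]):
                    dy = layer.backward(dy)
            if self._gain_map is not None:
                dy = dy * self._gain_map[None, :, :, None]
            grads.append(dy)
        return grads

    # -- training ------------------------------------------------------------

    def classify_logits(self, images, gain_map=None) -> np.ndarray:
        return self.head.forward(self.encode(images, gain_map))

    def state_dict(self) -> dict:
        state = {}
        for bi, block in enumerate(self.blocks):
            conv = block[0]
            state[f"block{bi}.W"] = conv.W
            if conv.b is not None:
                state[f"block{bi}.b"] = conv.b
        state["head.W"] = self.head.W
        state["head.b"] = self.head.b
        return state

    def load_state_dict(self, state: dict):
        for bi, block in enumerate(self.blocks):
            conv = block[0]
            conv.W = np.asarray(state[f"block{bi}.W"], DTYPE)
            if conv.b is not None:
                conv.b = np.asarray(state[f"block{bi}.b"], DTYPE)
        self.head.W = np.asarray(state["head.W"], DTYPE)
        self.head.b = np.asarray(state["head.b"], DTYPE)

    def copy(self) -> "Observer":
        other = Observer(self.config)
        other.load_state_dict({k: v.copy() for k, v in self.state_dict().items()})
        other.post_block_hooks = dict(self.post_block_hooks)
        return other


def save_checkpoint(observer: Observer, path):
    """Binary weight checkpoint plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **observer.state_dict())
    sidecar = path.with_suffix(".json")
    cfg = observer.config.__dict__.copy()
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> Observer:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg = {k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg.items()}
    obs = Observer(ObserverConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        obs.load_state_dict(dict(f))
    return obs


def upscale_to_input(pixels: np.ndarray, input_side: int) -> np.ndarray:
    """Nearest-neighbour upscale of a base image to the observer's input size
    (a base image fills the whole input, the way single full-size images do
    during readout training)."""
    side = pixels.shape[0]
    if input_side % side:
        raise ValueError(f"input side {input_side} not a multiple of image side {side}")
    f = input_side // side
    if f == 1:
        return np.asarray(pixels, DTYPE)
    return np.repeat(np.repeat(pixels, f, axis=0), f, axis=1).astype(DTYPE)


def library_as_batch(library: Library, input_side: int):
    """(images, labels) arrays with base images upscaled to the input size."""
    X = np.stack([upscale_to_input(im.pixels, input_side) for im in library.images])
    y = np.array([im.category_id for im in library.images], np.int64)
    return X, y


def train_observer(observer: Observer, library: Library, epochs: int = 10,
                   lr: float = 1e-3, batch_size: int = 32, seed: int = 0,
                   verbose: bool = False) -> dict:
    """Train the observer's conv blocks and classification head to label base
    images by category (softmax cross-entropy, Adam).

    Deterministic given (observer config, library, seed).  Returns a history
    dict with per-epoch loss and held-out accuracy computed on a 1/6
    validation split.
    """
    if library.n_categories < 2:
        raise ValueError("need at least 2 categories to train")
    X, y = library_as_batch(library, observer.config.input_side)
    rng = np.random.default_rng([seed, 17])
    order = rng.permutation(len(X))
    n_val = max(len(X) // 6, 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    layers = [b[0] for b in observer.blocks] + [observer.head]
    opt = Adam(layers, lr=lr)
    history = {"loss": [], "val_accuracy": []}
    for epoch in range(epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            acts = observer.forward(X[idx])
            logits = observer.head.forward(acts.encoding)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training loss diverged (non-finite)")
            denc = observer.head.backward(dlogits)
            # encoding = spatial mean of the final map
            fm = acts.final_map
            dy = np.broadcast_to(
                denc[:, None, None, :] / (fm.shape[1] * fm.shape[2]), fm.shape
            ).astype(DTYPE)
            for block in reversed(observer.blocks):
                for layer in reversed(block):
                    dy = layer.backward(dy)
            opt.step()
            losses.append(loss)
        pred = observer.classify_logits(X[val_idx]).argmax(axis=1)
        acc = float(np.mean(pred == y[val_idx]))
        history["loss"].append(float(np.mean(losses)) if losses else np.nan)
        history["val_accuracy"].append(acc)
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss={history['loss'][-1]:.4f} "
                  f"val_acc={acc:.3f}")
    return history


# ---------------------------------------------------------------------------
# readouts and evaluation
# ---------------------------------------------------------------------------

@dataclass
class ReadoutModel:
    """Per-category linear presence classifier over the encoding."""

    category_id: int
    coef: np.ndarray
    intercept: float
    l2_strength: float = 1.0
    trained_on: str = ""

    def score(self, encodings: np.ndarray) -> np.ndarray:
        return np.asarray(encodings, np.float64) @ self.coef + self.intercept


def train_readout(encodings, labels, l2_strength: float = 1.0,
                  category_id: int = -1, trained_on: str = "") -> ReadoutModel:
    """Logistic regression (L2, liblinear) on encoding vectors.

    ``labels`` is a boolean/0-1 presence vector; both classes must occur.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("readout training needs both present and absent examples")
    clf = LogisticRegression(C=l2_strength, penalty="l2", solver="liblinear",
                             random_state=0)
    clf.fit(np.asarray(encodings, np.float64), labels)
    return ReadoutModel(category_id, clf.coef_.ravel().copy(),
                        float(clf.intercept_[0]), l2_strength, trained_on)


def train_category_readouts(observer: Observer, library: Library, seed: int = 0,
                            l2_strength: float = 1.0, batch_size: int = 64,
                            **encode_kw) -> dict:
    """One presence readout per category, trained on held-out base images
    (present = that category's images, absent = an equal-size sample of the
    other categories').  ``encode_kw`` selects the representation (e.g.
    ``flatten=True`` for the unpooled readout, or a ``keep_mask``) and must
    then be used consistently at evaluation time."""
    X, y = library_as_batch(library, observer.config.input_side)
    enc = batched_encode(observer, X, batch_size=batch_size, **encode_kw)
    rng = np.random.default_rng([seed, 23])
    readouts = {}
    for cat in library.category_ids():
        pos = np.flatnonzero(y == cat)
        neg_all = np.flatnonzero(y != cat)
        neg = rng.choice(neg_all, size=min(len(pos), len(neg_all)), replace=False)
        idx = np.concatenate([pos, neg])
        readouts[cat] = train_readout(enc[idx], (y[idx] == cat), l2_strength,
                                      category_id=cat, trained_on="base-images")
    return readouts


def auc(scores_present, scores_absent) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula:
    P(score_present > score_absent) + 0.5 * P(tie)."""
    sp = np.asarray(scores_present, np.float64)
    sa = np.asarray(scores_absent, np.float64)
    if sp.size == 0 or sa.size == 0:
        raise ValueError("auc requires non-empty score lists")
    ranks = rankdata(np.concatenate([sp, sa]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2
    return float(u / (sp.size * sa.size))


def batched_encode(observer: Observer, images: np.ndarray, gain_map=None,
                   forward_fn=None, final_map_transform=None, keep_mask=None,
                   flatten: bool = False, batch_size: int = 64) -> np.ndarray:
    """Encode images in batches; hooks cover the model-variant conditions.

    ``forward_fn(images, gain_map=...) -> LayerActivations`` overrides the
    plain forward (quadrant-isolated or rewired models);
    ``final_map_transform`` edits the final feature map (propagated-gain
    multiply/divide); ``keep_mask`` (h, w) bool restricts the readout to a
    spatial region (masked readout); ``flatten=True`` keeps the spatial
    layout (concatenated kept-position features, the unpooled readout
    variant) instead of average pooling.
    """
    fwd = forward_fn if forward_fn is not None else observer.forward
    encs = []
    for start in range(0, len(images), batch_size):
        acts = fwd(images[start:start + batch_size], gain_map=gain_map)
        fm = acts.final_map
        if final_map_transform is not None:
            fm = final_map_transform(fm)
        if keep_mask is not None:
            km = np.asarray(keep_mask, bool)
            if km.shape != fm.shape[1:3]:
                raise ValueError("keep_mask shape does not match final map")
            if not km.any():
                raise ValueError("keep_mask is empty")
            kept = fm[:, km, :]
        else:
            kept = fm.reshape(fm.shape[0], -1, fm.shape[3])
        if flatten:
            encs.append(kept.reshape(kept.shape[0], -1))
        else:
            encs.append(kept.mean(axis=1))
    return np.concatenate(encs)


@dataclass
class EvalResult:
    """Per-category performance with a bootstrap CI on the median."""

    per_category: dict
    condition: str = ""
    metric: str = "auc"
    ci: tuple = (np.nan, np.nan)

    @property
    def median(self) -> float:
        return float(np.median(list(self.per_category.values())))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "category": list(self.per_category.keys()),
            "condition": self.condition,
            self.metric: list(self.per_category.values()),
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
        })


def _median_ci(values, n_boot, seed):
    from .behavior import bootstrap_ci
    return bootstrap_ci(np.median, np.asarray(list(values), float),
                        n_boot=n_boot, seed=seed)


def grids_as_batch(grids: Sequence[CompositeGrid]) -> np.ndarray:
    return np.stack([g.pixels for g in grids]).astype(DTYPE)


def evaluate_detection(observer: Observer, readouts: dict, stimulus_set,
                       condition: str = "", n_boot: int = 1000, seed: int = 0,
                       **encode_kw) -> EvalResult:
    """Per-category detection AUC on a composite set.

    For each grid the target category's readout scores the encoding; AUC
    compares target-present vs target-absent scores within category.
    ``encode_kw`` passes through to :func:`batched_encode` (gain_map,
    forward_fn, final_map_transform, keep_mask).
    """
    cats = sorted({g.target_category for g in stimulus_set.grids})
    missing = [c for c in cats if c not in readouts]
    if missing:
        raise ValueError(f"no readout trained for categories {missing}")
    images = grids_as_batch(stimulus_set.grids)
    enc = batched_encode(observer, images, **encode_kw)
    per_cat = {}
    for cat in cats:
        idx = [i for i, g in enumerate(stimulus_set.grids) if g.target_category == cat]
        present = [i for i in idx if stimulus_set.grids[i].target_present]
        absent = [i for i in idx if not stimulus_set.grids[i].target_present]
        scores = readouts[cat].score(enc)
        per_cat[cat] = auc(scores[present], scores[absent])
    ci = _median_ci(per_cat.values(), n_boot, seed)
    return EvalResult(per_cat, condition=condition, metric="auc", ci=ci)


def evaluate_discrimination(observer: Observer, readouts: dict, pairs,
                            condition: str = "", n_boot: int = 1000,
                            seed: int = 0, **encode_kw) -> EvalResult:
    """Two-alternative discrimination accuracy per category pair.

    For each composite pair the cued category's readout scores both grids and
    the larger score is chosen (ties count 1/2).  Each pair contributes two
    trials (A cued, then B cued).
    """
    all_grids = [g for p in pairs for g in (p.grid_a, p.grid_b)]
    images = grids_as_batch(all_grids)
    enc = batched_encode(observer, images, **encode_kw)
    correct = {}
    for i, p in enumerate(pairs):
        ea, eb = enc[2 * i], enc[2 * i + 1]
        key = (p.category_a, p.category_b)
        trials = correct.setdefault(key, [])
        sa = readouts[p.category_a].score(ea[None])[0]
        sb = readouts[p.category_a].score(eb[None])[0]
        trials.append(1.0 if sa > sb else (0.5 if sa == sb else 0.0))
        sa = readouts[p.category_b].score(ea[None])[0]
        sb = readouts[p.category_b].score(eb[None])[0]
        trials.append(1.0 if sb > sa else (0.5 if sa == sb else 0.0))
    per_pair = {k: float(np.mean(v)) for k, v in correct.items()}
    ci = _median_ci(per_pair.values(), n_boot, seed)
    return EvalResult(per_pair, condition=condition, metric="accuracy", ci=ci)


def masked_readout(observer: Observer, readouts: dict, stimulus_set,
                   keep_region, condition: str = "masked-readout",
                   n_boot: int = 1000, seed: int = 0, **kw) -> EvalResult:
    """Detection with readout restricted to a spatial region of the final map
    (e.g. the NW positions), reusing the pooled prediction layers — zeroing
    the excluded positions before average pooling only rescales the pooled
    vector, which leaves the linear readout's ranking (and hence AUC) intact.
    """
    side = observer.config.block_sides()[-1]
    if isinstance(keep_region, tuple) and len(keep_region) == 2 \
            and all(isinstance(s, slice) for s in keep_region):
        mask = np.zeros((side, side), bool)
        mask[keep_region] = True
    else:
        mask = np.asarray(keep_region, bool)
    if not mask.any():
        raise ValueError("masked readout requires a non-empty keep region")
    return evaluate_detection(observer, readouts, stimulus_set,
                              condition=condition, n_boot=n_boot, seed=seed,
                              keep_mask=mask, **kw)
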