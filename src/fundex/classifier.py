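"""Downstream image classifier: data splitting and a small vision
transformer trained under the stated recipe.

The protocol: each dataset is split 80/20 into training and validation
(only real images are ever eligible — synthetics join later, on the
training side only); images are resized to a uniform square side with
intensities in [0, 1]; the transformer is optimised with AdamW
(lr 6e-4, weight decay 6e-2), batch size 16, cross-entropy with 0.1 label
smoothing.  ``model_scale="toy"`` selects a small CPU-feasible transformer
for fixture-scale experiments; ``"full"`` builds a standard full-size
variant with the same code path.

The augmentation effect being measured lives in the training data, not the
backbone, so the backbone is deliberately configurable.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from skimage.transform import resize as _resize

from .data import ImageDataset
from .metrics import roc_auc
from .nn import AdamW, LayerNorm, Linear, Module, Tensor, no_grad

__all__ = [
    "SplitSpec", "TrainRecipe", "ClassifierState",
    "split_dataset", "subsample_train", "train_classifier", "predict",
]


# ---------------------------------------------------------------------------
# splitting and subsampling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(data: ImageDataset, spec: SplitSpec
                  ) -> tuple[ImageDataset, ImageDataset]:
    """Disjoint (train, validation) split with ⌊f·N⌋ training images.

    Only real images may be split; synthetic data must never reach the
    validation side, so a dataset containing synthetics is rejected.
    """
    n = len(data)
    if n < 5:
        raise ValueError(f"need at least 5 images to split, got {n}")
    if any(im.source != "real" for im in data):
        raise ValueError("split operates on real images only; expand after splitting")
    n_train = int(math.floor(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        y = data.labels
        train_idx: list[int] = []
        # per-class quotas proportional to class size; remainder drawn from
        # the largest fractional parts so the total is exactly ⌊f·N⌋
        classes = np.unique(y)
        quota = {c: spec.train_fraction * (y == c).sum() for c in classes}
        base = {c: int(math.floor(quota[c])) for c in classes}
        short = n_train - sum(base.values())
        for c in sorted(classes, key=lambda c: quota[c] - base[c], reverse=True):
            if short > 0:
                base[c] += 1
                short -= 1
        for c in classes:
            idx_c = np.flatnonzero(y == c)
            perm = rng.permutation(idx_c)
            train_idx.extend(perm[: base[c]])
        train_idx = sorted(train_idx)
    else:
        perm = rng.permutation(n)
        train_idx = sorted(perm[:n_train])
    val_idx = sorted(set(range(n)) - set(train_idx))
    return data.subset(train_idx), data.subset(val_idx)


def subsample_train(train: ImageDataset, fraction: float,
                    seed: int = 0) -> ImageDataset:
    """Seeded uniform draw of ⌊fraction·N⌋ training images.

    Subsamples are nested under a shared seed: the draw takes a prefix of
    one seeded permutation, so the 10 % subsample is contained in the 20 %
    one, and fraction 1.0 is the identity (up to order).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = len(train)
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValueError(f"fraction {fraction} selects no images from {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return train.subset(sorted(perm[:k]))


# ---------------------------------------------------------------------------
# recipe and model
# ---------------------------------------------------------------------------

_SCALES = {
    # dim, depth, heads, mlp_ratio, patch
    "toy": dict(dim=32, depth=2, heads=2, mlp_ratio=2, patch=8),
    "full": dict(dim=768, depth=12, heads=12, mlp_ratio=4, patch=16),
}


@dataclasses.dataclass
class TrainRecipe:
    input_side: int = 224
    batch_size: int = 16
    learning_rate: float = 6e-4
    weight_decay: float = 6e-2
    label_smoothing: float = 0.1
    epochs: int = 20
    model_scale: str = "toy"
    balance: str = "none"  # "none" | "downsample" | "weighted"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.label_smoothing < 0.5):
            raise ValueError("label_smoothing must lie in [0, 0.5)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.model_scale not in _SCALES:
            raise ValueError(f"model_scale must be one of {sorted(_SCALES)}")
        if self.balance not in ("none", "downsample", "weighted"):
            raise ValueError("balance must be none, downsample or weighted")
        if self.input_side % _SCALES[self.model_scale]["patch"] != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by patch size "
                f"{_SCALES[self.model_scale]['patch']}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainRecipe":
        return cls(**d)


class _Attention(Module):
    def __init__(self, dim: int, heads: int, *, rng):
        self.heads, self.dh = heads, dim // heads
        self.q = Linear(dim, dim, rng=rng)
        self.k = Linear(dim, dim, rng=rng)
        self.v = Linear(dim, dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, dh = self.heads, self.dh

        def heads_view(z: Tensor) -> Tensor:
            return z.reshape(n, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = heads_view(self.q(x)), heads_view(self.k(x)), heads_view(self.v(x))
        attn = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        out = attn.softmax().matmul(v)  # (n, h, t, dh)
        out = out.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.proj(out)


class _MLP(Module):
    def __init__(self, dim: int, hidden: int, *, rng):
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).leaky_relu(0.01))


class _Block(Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: int, *, rng):
        self.ln1, self.ln2 = LayerNorm(dim), LayerNorm(dim)
        self.attn = _Attention(dim, heads, rng=rng)
        self.mlp = _MLP(dim, dim * mlp_ratio, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))


class VisionTransformer(Module):
    """Patch-token transformer with mean pooling and a 2-class head."""

    def __init__(self, input_side: int, scale: str, *, rng: np.random.Generator):
        s = _SCALES[scale]
        self.patch = s["patch"]
        self.dim = s["dim"]
        self.tokens = (input_side // self.patch) ** 2
        self.embed = Linear(3 * self.patch**2, self.dim, rng=rng)
        self.pos = Tensor(rng.normal(0, 0.02, size=(self.tokens, self.dim)),
                          requires_grad=True)
        self.blocks = [_Block(self.dim, s["heads"], s["mlp_ratio"], rng=rng)
                       for _ in range(s["depth"])]
        self.norm = LayerNorm(self.dim)
        self.head = Linear(self.dim, 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 3, S, S) → logits (N, 2)."""
        n, c, s, _ = x.shape
        p = self.patch
        g = s // p
        tok = (
            x.transpose(0, 2, 3, 1)
            .reshape(n, g, p, g, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, g * g, p * p * c)
        )
        h = self.embed(tok) + self.pos
        for b in self.blocks:
            h = b(h)
        return self.head(self.norm(h).mean(axis=1))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class ClassifierState:
    def __init__(self, model: VisionTransformer, recipe: TrainRecipe):
        self.model = model
        self.recipe = recipe
        self.train_log: list[float] = []  # per-step loss
        self.val_auc_history: list[float] = []


def _preprocess(data: ImageDataset, side: int) -> np.ndarray:
    """Resize to side×side, [0, 1] intensities, NCHW."""
    out = np.empty((len(data), 3, side, side))
    for i, im in enumerate(data):
        px = im.pixels
        if px.shape[0] != side or px.shape[1] != side:
            px = _resize(px, (side, side), anti_aliasing=True)
        out[i] = np.clip(px, 0.0, 1.0).transpose(2, 0, 1)
    return out


def audit_no_leakage(train: ImageDataset) -> None:
    """Every synthetic in the training set must derive from a real image
    that is itself in the training set."""
    real_ids = {im.id for im in train if im.source == "real"}
    for im in train:
        if im.source == "synthetic" and im.origin_id not in real_ids:
            raise ValueError(
                f"synthetic {im.id} derives from {im.origin_id!r}, which is "
                "not in the training set (possible validation leak)"
            )


def train_classifier(train: ImageDataset, recipe: TrainRecipe,
                     validation: ImageDataset | None = None) -> ClassifierState:
    """Train the transformer on ``train`` under ``recipe``.

    If ``validation`` is given, the validation AUC is tracked per epoch and
    the best-AUC parameters are restored at the end.  Class imbalance can
    be handled by downsampling the majority class or by inverse-frequency
    loss weights (``recipe.balance``).
    """
    y = train.labels
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    audit_no_leakage(train)

    rng = np.random.default_rng([recipe.seed, 0xC1F])
    if recipe.balance == "downsample":
        n0, n1 = (y == 0).sum(), (y == 1).sum()
        keep_n = min(n0, n1)
        keep = []
        for c in (0, 1):
            idx_c = np.flatnonzero(y == c)
            keep.extend(rng.choice(idx_c, size=keep_n, replace=False))
        train = train.subset(sorted(keep))
        y = train.labels

    class_weights = None
    if recipe.balance == "weighted":
        n = len(y)
        class_weights = np.array([n / (2.0 * max((y == c).sum(), 1))
                                  for c in (0, 1)])

    x = _preprocess(train, recipe.input_side)
    model = VisionTransformer(recipe.input_side, recipe.model_scale,
                              rng=np.random.default_rng([recipe.seed, 0x111]))
    state = ClassifierState(model, recipe)
    opt = AdamW(model.parameters(), lr=recipe.learning_rate,
                weight_decay=recipe.weight_decay)

    xv = yv = None
    if validation is not None:
        xv = _preprocess(validation, recipe.input_side)
        yv = validation.labels
    best_auc, best_params = -np.inf, None

    n = len(train)
    bs = min(recipe.batch_size, n)
    for epoch in range(recipe.epochs):
        order = rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            logits = model(Tensor(x[idx]))
            loss = logits.cross_entropy(y[idx], recipe.label_smoothing,
                                        class_weights)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(f"non-finite training loss: {val}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.train_log.append(val)
        if xv is not None and np.unique(yv).size == 2:
            auc = roc_auc(_scores(model, xv), yv)
            state.val_auc_history.append(auc)
            if auc > best_auc:
                best_auc = auc
                best_params = [a.copy() for a in model.state_arrays()]
    if best_params is not None:
        model.load_state_arrays(best_params)
    return state


def _scores(model: VisionTransformer, x: np.ndarray,
            batch: int = 64) -> np.ndarray:
    out = np.empty(x.shape[0])
    with no_grad():
        for start in range(0, x.shape[0], batch):
            logits = model(Tensor(x[start : start + batch]))
            out[start : start + batch] = logits.softmax().data[:, 1]
    return out


def predict(state: ClassifierState, data: ImageDataset) -> np.ndarray:
    """Case probability per image, deterministic in evaluation mode."""
    x = _preprocess(data, state.recipe.input_side)
    return _scores(state.model, x)


def save_classifier(state: ClassifierState, path) -> None:
    import json
    from pathlib import Path

    payload = {
        "recipe_json": np.array(json.dumps(state.recipe.to_dict())),
        "train_log": np.array(state.train_log),
        "val_auc_history": np.array(state.val_auc_history),
    }
    for i, a in enumerate(state.model.state_arrays()):
        payload[f"p_{i}"] = a
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **payload)


def load_classifier(path) -> ClassifierState:
    import json

    with np.load(path, allow_pickle=False) as z:
        recipe = TrainRecipe.from_dict(json.loads(str(z["recipe_json"])))
        model = VisionTransformer(recipe.input_side, recipe.model_scale,
                                  rng=np.random.default_rng(0))
        n = len(model.parameters())
        model.load_state_arrays([z[f"p_{i}"] for i in range(n)])
        state = ClassifierState(model, recipe)
        state.train_log = [float(x) for x in z["train_log"]]
        state.val_auc_history = [float(x) for x in z["val_auc_history"]]
    return state
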