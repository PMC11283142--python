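"""Dual-level patch autoencoder.

Level 1 is a patch codec: it maps each 12×12×3 tile of an image to a 48-d
embedding and back.  An image of side 12·G therefore becomes a 48×G×G latent
grid (48 channels = patch embedding size).  Level 2 is a codec over that
latent grid: for a 96×96 image (G = 8) it compresses the 48×8×8 latent to a
single 1024-d embedding vector and back.  Composing the two levels encodes a
96×96×3 image into 1024 numbers.

The two levels are trained independently — Level 1 on raw 12×12 patches,
Level 2 on the frozen latents Level 1 produces — which keeps the memory
footprint of either stage small; a ``joint`` mode fine-tunes both through
the full pixel reconstruction.  The training loss is the mean absolute
discrepancy between the codec's input and its reconstruction, optimised
with AdamW (lr 3e-4, weight decay 5e-7) under a leaky-rectifier activation
throughout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .blocks import ContractionBlock, BlockConfig, ExpansionBlock
from .data import ImageDataset
from .nn import AdamW, Conv2d, ConvTranspose2d, Module, Tensor, no_grad

__all__ = [
    "CodecConfig", "PatchGrid", "CodecState", "tile_patches", "untile_patches",
    "encode_level1", "decode_level1", "encode_level2", "decode_level2",
    "encode_full", "decode_full", "encode_full_batch", "decode_full_batch",
    "train_codec", "init_codec", "reconstruction_mae",
    "save_checkpoint", "load_checkpoint",
]

PATCH_SIZE = 12
PATCH_EMBED_DIM = 48


@dataclasses.dataclass
class CodecConfig:
    """Architecture and training hyperparameters.

    ``patch_size`` and ``patch_embed_dim`` are fixed constants of the
    design (12 and 48).  ``level2_embed_dim`` defaults to 16·G² where
    G = image_size / 12, which gives the canonical 1024 at image_size 96.
    """

    image_size: int = 96
    patch_size: int = PATCH_SIZE
    patch_embed_dim: int = PATCH_EMBED_DIM
    level2_embed_dim: int | None = None
    learning_rate: float = 3e-4
    weight_decay: float = 5e-7
    loss: str = "mae"
    batch_size: int = 64
    fp16: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.patch_size != PATCH_SIZE or self.patch_embed_dim != PATCH_EMBED_DIM:
            raise ValueError(
                f"patch codec is fixed at {PATCH_SIZE}×{PATCH_SIZE} → "
                f"{PATCH_EMBED_DIM}-d embeddings"
            )
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} is not a multiple of {self.patch_size}"
            )
        g = self.grid_side
        if g & (g - 1) != 0:
            raise ValueError(f"grid side {g} must be a power of two")
        if self.level2_embed_dim is None:
            self.level2_embed_dim = 16 * g * g
        if self.loss != "mae":
            raise ValueError("only the mean-absolute-error loss is supported")

    @property
    def grid_side(self) -> int:
        return self.image_size // self.patch_size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CodecConfig":
        return cls(**d)


@dataclasses.dataclass
class PatchGrid:
    """Row-major G×G grid of 12×12×3 tiles; tiling is lossless."""

    patches: np.ndarray  # (G, G, p, p, 3)

    @property
    def grid_side(self) -> int:
        return self.patches.shape[0]


def tile_patches(image: np.ndarray, patch_size: int = PATCH_SIZE) -> PatchGrid:
    """Split an H×W×3 image into non-overlapping patches, row-major."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    if h % patch_size or w % patch_size:
        raise ValueError(f"image {h}×{w} not divisible by patch size {patch_size}")
    gh, gw = h // patch_size, w // patch_size
    grid = image.reshape(gh, patch_size, gw, patch_size, 3).transpose(0, 2, 1, 3, 4)
    return PatchGrid(patches=np.ascontiguousarray(grid))


def untile_patches(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`tile_patches`."""
    gh, gw, p, _, _ = grid.patches.shape
    return grid.patches.transpose(0, 2, 1, 3, 4).reshape(gh * p, gw * p, 3)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class Level1Codec(Module):
    """12×12×3 patch ↔ 48-d embedding (applied independently per patch)."""

    def __init__(self, *, rng: np.random.Generator):
        d = PATCH_EMBED_DIM
        # encoder: contraction group (two blocks, 12→6→3) + 3×3 head to 1×1
        self.enc_b1 = ContractionBlock(BlockConfig(3, d // 2), rng=rng)
        self.enc_b2 = ContractionBlock(BlockConfig(d // 2, d), rng=rng)
        self.enc_head = Conv2d(d, d, 3, stride=1, padding=0, rng=rng)
        # decoder: 3×3 transposed head (1→3) + expansion group (3→6→12)
        self.dec_head = ConvTranspose2d(d, d, 3, stride=1, padding=0, rng=rng)
        self.dec_b1 = ExpansionBlock(BlockConfig(d, d // 2), rng=rng)
        self.dec_b2 = ExpansionBlock(BlockConfig(d // 2, d // 4), rng=rng)
        self.dec_out = Conv2d(d // 4, 3, 1, rng=rng)

    def encode(self, patches: Tensor) -> Tensor:
        """(M, 3, 12, 12) → (M, 48)."""
        h = self.enc_b2(self.enc_b1(patches))
        h = self.enc_head(h)  # (M, 48, 1, 1)
        return h.reshape(h.shape[0], PATCH_EMBED_DIM)

    def decode(self, emb: Tensor) -> Tensor:
        """(M, 48) → (M, 3, 12, 12), intensities in [0, 1]."""
        h = emb.reshape(emb.shape[0], PATCH_EMBED_DIM, 1, 1)
        h = self.dec_head(h)
        h = self.dec_b2(self.dec_b1(h))
        return self.dec_out(h).sigmoid()


class Level2Codec(Module):
    """48×G×G latent grid ↔ D-vector (D = 1024 at G = 8).

    Contraction blocks halve the grid (channels doubling from 48) down to a
    2×2 map, then a full-support head convolution produces the embedding;
    the decoder mirrors this with transposed convolutions.
    """

    def __init__(self, grid_side: int, embed_dim: int, *, rng: np.random.Generator):
        self.grid_side, self.embed_dim = grid_side, embed_dim
        n_blocks = max(0, int(np.log2(grid_side)) - 1)
        chs = [PATCH_EMBED_DIM * (2**i) for i in range(n_blocks + 1)]
        self.enc_blocks = [
            ContractionBlock(BlockConfig(chs[i], chs[i + 1]), rng=rng)
            for i in range(n_blocks)
        ]
        head_k = grid_side // (2**n_blocks)  # 2, or 1 when grid_side == 1
        self.enc_head = Conv2d(chs[-1], embed_dim, head_k, rng=rng)
        self.dec_head = ConvTranspose2d(embed_dim, chs[-1], head_k, rng=rng)
        self.dec_blocks = [
            ExpansionBlock(BlockConfig(chs[i + 1], chs[i]), rng=rng)
            for i in reversed(range(n_blocks))
        ]
        self.dec_out = Conv2d(PATCH_EMBED_DIM, PATCH_EMBED_DIM, 1, rng=rng)

    def encode(self, latent: Tensor) -> Tensor:
        """(N, 48, G, G) → (N, D)."""
        h = latent
        for b in self.enc_blocks:
            h = b(h)
        h = self.enc_head(h)
        return h.reshape(h.shape[0], self.embed_dim)

    def decode(self, emb: Tensor) -> Tensor:
        """(N, D) → (N, 48, G, G)."""
        h = emb.reshape(emb.shape[0], self.embed_dim, 1, 1)
        h = self.dec_head(h)
        for b in self.dec_blocks:
            h = b(h)
        return self.dec_out(h)


# ---------------------------------------------------------------------------
# state, checkpointing
# ---------------------------------------------------------------------------


class CodecState:
    """Trained (or initialised) parameters of both levels plus the log."""

    def __init__(self, config: CodecConfig):
        self.config = config
        rng1 = np.random.default_rng([config.seed, 1])
        rng2 = np.random.default_rng([config.seed, 2])
        self.level1 = Level1Codec(rng=rng1)
        self.level2 = Level2Codec(config.grid_side, config.level2_embed_dim, rng=rng2)
        self.training_step = 0
        self.loss_history: list[float] = []
        self.trained_levels: set[int] = set()

    @property
    def is_trained(self) -> bool:
        return bool(self.trained_levels)

    def require_trained(self) -> None:
        if not self.is_trained:
            raise RuntimeError("codec has not been trained; call train_codec first")


def save_checkpoint(state: CodecState, path: str | Path) -> None:
    """Self-describing archive: config JSON + parameter arrays + log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.float16 if state.config.fp16 else np.float64
    payload = {
        "format_version": np.array(1),
        "config_json": np.array(json.dumps(state.config.to_dict())),
        "training_step": np.array(state.training_step),
        "loss_history": np.array(state.loss_history, dtype=np.float64),
        "trained_levels": np.array(sorted(state.trained_levels), dtype=np.int64),
    }
    for i, a in enumerate(state.level1.state_arrays()):
        payload[f"l1_{i}"] = a.astype(dtype)
    for i, a in enumerate(state.level2.state_arrays()):
        payload[f"l2_{i}"] = a.astype(dtype)
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> CodecState:
    with np.load(Path(path), allow_pickle=False) as z:
        config = CodecConfig.from_dict(json.loads(str(z["config_json"])))
        state = CodecState(config)
        n1 = len(state.level1.parameters())
        n2 = len(state.level2.parameters())
        state.level1.load_state_arrays([z[f"l1_{i}"] for i in range(n1)])
        state.level2.load_state_arrays([z[f"l2_{i}"] for i in range(n2)])
        state.training_step = int(z["training_step"])
        state.loss_history = [float(x) for x in z["loss_history"]]
        state.trained_levels = {int(x) for x in z["trained_levels"]}
    return state


# ---------------------------------------------------------------------------
# functional encode/decode surface
# ---------------------------------------------------------------------------


def _check_image(image: np.ndarray, config: CodecConfig) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got {image.shape}")
    return image


def encode_level1(grid: PatchGrid, state: CodecState) -> np.ndarray:
    """PatchGrid → latent grid (48, G, G); patches encoded independently."""
    g = grid.grid_side
    flat = grid.patches.reshape(-1, PATCH_SIZE, PATCH_SIZE, 3).transpose(0, 3, 1, 2)
    with no_grad():
        emb = state.level1.encode(Tensor(flat)).data  # (G*G, 48)
    return np.ascontiguousarray(emb.reshape(g, g, PATCH_EMBED_DIM).transpose(2, 0, 1))


def decode_level1(latent: np.ndarray, state: CodecState) -> np.ndarray:
    """Latent grid (48, G, G) → image (12G, 12G, 3) in [0, 1]."""
    latent = np.asarray(latent, dtype=np.float64)
    if latent.ndim != 3 or latent.shape[0] != PATCH_EMBED_DIM:
        raise ValueError(f"latent must be ({PATCH_EMBED_DIM}, G, G), got {latent.shape}")
    g = latent.shape[1]
    emb = latent.transpose(1, 2, 0).reshape(-1, PATCH_EMBED_DIM)
    with no_grad():
        patches = state.level1.decode(Tensor(emb)).data  # (G*G, 3, 12, 12)
    grid = PatchGrid(patches.transpose(0, 2, 3, 1).reshape(
        g, g, PATCH_SIZE, PATCH_SIZE, 3))
    return untile_patches(grid)


def encode_level2(latent: np.ndarray, state: CodecState) -> np.ndarray:
    """Latent grid (48, G, G) → embedding vector (D,)."""
    latent = np.asarray(latent, dtype=np.float64)
    g = state.config.grid_side
    if latent.shape != (PATCH_EMBED_DIM, g, g):
        raise ValueError(
            f"latent shape {latent.shape} does not match config "
            f"({PATCH_EMBED_DIM}, {g}, {g})"
        )
    with no_grad():
        emb = state.level2.encode(Tensor(latent[None])).data[0]
    return emb


def decode_level2(embedding: np.ndarray, state: CodecState) -> np.ndarray:
    """Embedding vector (D,) → latent grid (48, G, G)."""
    embedding = np.asarray(embedding, dtype=np.float64)
    d = state.config.level2_embed_dim
    if embedding.shape != (d,):
        raise ValueError(f"embedding shape {embedding.shape}, expected ({d},)")
    with no_grad():
        latent = state.level2.decode(Tensor(embedding[None])).data[0]
    return latent


def encode_full(image: np.ndarray, state: CodecState) -> np.ndarray:
    """Image (12G×12G×3) → composed embedding (D,)."""
    image = _check_image(image, state.config)
    return encode_level2(encode_level1(tile_patches(image), state), state)


def decode_full(embedding: np.ndarray, state: CodecState) -> np.ndarray:
    """Composed embedding (D,) → image (12G×12G×3) in [0, 1]."""
    return decode_level1(decode_level2(embedding, state), state)


def encode_full_batch(images: np.ndarray, state: CodecState) -> np.ndarray:
    """(N, 12G, 12G, 3) → (N, D); batched for throughput."""
    images = np.asarray(images, dtype=np.float64)
    n = images.shape[0]
    g = state.config.grid_side
    p = PATCH_SIZE
    patches = images.reshape(n, g, p, g, p, 3).transpose(0, 1, 3, 2, 4, 5)
    flat = patches.reshape(n * g * g, p, p, 3).transpose(0, 3, 1, 2)
    with no_grad():
        emb = state.level1.encode(Tensor(flat)).data
        latents = emb.reshape(n, g, g, PATCH_EMBED_DIM).transpose(0, 3, 1, 2)
        return state.level2.encode(Tensor(latents)).data


def decode_full_batch(embeddings: np.ndarray, state: CodecState) -> np.ndarray:
    """(N, D) → (N, 12G, 12G, 3)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    n = embeddings.shape[0]
    g = state.config.grid_side
    p = PATCH_SIZE
    with no_grad():
        latents = state.level2.decode(Tensor(embeddings)).data  # (N, 48, G, G)
        emb1 = latents.transpose(0, 2, 3, 1).reshape(n * g * g, PATCH_EMBED_DIM)
        patches = state.level1.decode(Tensor(emb1)).data  # (N*G*G, 3, 12, 12)
    patches = patches.transpose(0, 2, 3, 1).reshape(n, g, g, p, p, 3)
    return patches.transpose(0, 1, 3, 2, 4, 5).reshape(n, g * p, g * p, 3)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _all_patches(dataset: ImageDataset, config: CodecConfig) -> np.ndarray:
    """Every patch of every image, NCHW, shuffle-ready."""
    stacks = []
    for im in dataset:
        grid = tile_patches(im.pixels, config.patch_size)
        g = grid.grid_side
        stacks.append(grid.patches.reshape(g * g, PATCH_SIZE, PATCH_SIZE, 3))
    return np.concatenate(stacks).transpose(0, 3, 1, 2)


def _frozen_latents(dataset: ImageDataset, state: CodecState) -> np.ndarray:
    """(N, 48, G, G) latents from the frozen Level-1 encoder."""
    out = []
    for im in dataset:
        out.append(encode_level1(tile_patches(im.pixels), state))
    return np.stack(out)


def train_codec(dataset: ImageDataset, config: CodecConfig,
                level: int | str = 1, *, steps: int = 500,
                state: CodecState | None = None,
                seed: int | None = None) -> CodecState:
    """Train the codec on ``dataset`` and return its state.

    ``level`` selects the stage: ``1`` trains the patch codec on raw
    patches; ``2`` trains the latent codec on frozen Level-1 latents
    (Level-1 parameters are never touched); ``"joint"`` optimises both
    through the full pixel reconstruction.  The loss is always the mean
    absolute error between the stage's input and its reconstruction.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    if level not in (1, 2, "joint"):
        raise ValueError(f"level must be 1, 2 or 'joint', got {level!r}")
    for im in dataset:
        h, w, _ = im.shape
        if h != config.image_size or w != config.image_size:
            raise ValueError(
                f"image {im.id} is {h}×{w}, config expects "
                f"{config.image_size}×{config.image_size}"
            )
    if state is None:
        state = CodecState(config)
    rng = np.random.default_rng(
        config.seed if seed is None else seed)

    if level == 1:
        data = _all_patches(dataset, config)
        params = state.level1.parameters()
        forward = lambda xb: state.level1.decode(state.level1.encode(xb))
    elif level == 2:
        if 1 not in state.trained_levels:
            raise RuntimeError(
                "Level-2 training needs a trained Level-1 codec "
                "(train level 1 first, then pass its state)"
            )
        data = _frozen_latents(dataset, state)
        params = state.level2.parameters()
        forward = lambda xb: state.level2.decode(state.level2.encode(xb))
    else:  # joint: full pixel round-trip, both levels updated
        data = np.stack([im.pixels for im in dataset]).transpose(0, 3, 1, 2)
        params = state.level1.parameters() + state.level2.parameters()
        g, p = config.grid_side, PATCH_SIZE

        def forward(xb: Tensor) -> Tensor:
            n = xb.shape[0]
            patches = (
                xb.transpose(0, 2, 3, 1)
                .reshape(n, g, p, g, p, 3)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n * g * g, p, p, 3)
                .transpose(0, 3, 1, 2)
            )
            emb1 = state.level1.encode(patches)
            latents = emb1.reshape(n, g, g, PATCH_EMBED_DIM).transpose(0, 3, 1, 2)
            emb2 = state.level2.encode(latents)
            lat_rec = state.level2.decode(emb2)
            emb_rec = lat_rec.transpose(0, 2, 3, 1).reshape(n * g * g, PATCH_EMBED_DIM)
            patch_rec = state.level1.decode(emb_rec)
            return (
                patch_rec.transpose(0, 2, 3, 1)
                .reshape(n, g, g, p, p, 3)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, g * p, g * p, 3)
                .transpose(0, 3, 1, 2)
            )

    opt = AdamW(params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    n_items = data.shape[0]
    bs = min(config.batch_size, n_items)
    for step in range(steps):
        idx = rng.choice(n_items, size=bs, replace=False)
        xb = Tensor(data[idx])
        loss = forward(xb).mae(data[idx])
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss at step {state.training_step}: {val}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.training_step += 1
        state.loss_history.append(val)
    state.trained_levels.add(2 if level == 2 else 1)
    if level in (2, "joint"):
        state.trained_levels.add(2)
    return state


def init_codec(config: CodecConfig) -> CodecState:
    """Freshly initialised (untrained) codec state."""
    return CodecState(config)


def reconstruction_mae(dataset: ImageDataset, state: CodecState) -> float:
    """Mean absolute pixel error of the full round-trip over a dataset."""
    imgs = dataset.pixel_stack()
    rec = decode_full_batch(encode_full_batch(imgs, state), state)
    return float(np.mean(np.abs(rec - imgs)))
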