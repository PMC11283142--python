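"""Latent-perturbation synthesis and training-set expansion.

Synthetic variants of a real image are made by encoding it to its composed
embedding, perturbing the embedding, and decoding the result.  Three
perturbation kinds provide "different types" of variation:

``additive-gaussian``
    add seeded Gaussian noise of absolute scale ``magnitude`` elementwise;
``channel-scale``
    multiply each embedding coordinate by ``1 + magnitude·u`` with
    ``u ~ Uniform(-1, 1)``;
``latent-interpolate``
    move the embedding a fraction ``magnitude`` of the way toward the
    embedding of a reference image (a random same-class training image).

The expansion protocol generates three synthetics per real training image,
then selects uniformly at random exactly one third of the 3N candidates, so
the training set doubles: N real + N synthetic (100 % expansion).  Synthetic
images inherit the label of their source and record its id as provenance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .codec import CodecState, decode_full_batch, encode_full_batch
from .data import ImageDataset, LabeledImage

__all__ = [
    "PerturbSpec", "ExpansionPlan", "perturb_latent", "synthesize",
    "expand_dataset", "DEFAULT_MAGNITUDES",
]

PERTURB_KINDS = ("additive-gaussian", "channel-scale", "latent-interpolate")

# default magnitudes per kind, calibrated on fixture codecs so that the
# synthetic-vs-source deviation lands a small multiple above pure
# reconstruction error (see docs/methods.md)
DEFAULT_MAGNITUDES = {
    "additive-gaussian": 4.0,
    "channel-scale": 2.0,
    "latent-interpolate": 0.8,
}


@dataclasses.dataclass
class PerturbSpec:
    kind: str
    magnitude: float
    seed: int
    reference: np.ndarray | None = None  # required for latent-interpolate

    def __post_init__(self):
        if self.kind not in PERTURB_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")


@dataclasses.dataclass
class ExpansionPlan:
    """3×-generate / ⅓-select / 100 %-expand protocol."""

    per_image_count: int = 3
    selection_fraction: float = 1.0 / 3.0
    expansion_ratio: float = 1.0
    seed: int = 0
    magnitudes: dict | None = None

    def __post_init__(self):
        if abs(self.per_image_count * self.selection_fraction
               - self.expansion_ratio) > 1e-9:
            raise ValueError(
                "plan inconsistent: per_image_count × selection_fraction must "
                "equal expansion_ratio"
            )
        if self.magnitudes is None:
            self.magnitudes = dict(DEFAULT_MAGNITUDES)


def perturb_latent(embedding: np.ndarray, spec: PerturbSpec) -> np.ndarray:
    """Apply one seeded perturbation to an embedding vector.

    Magnitude 0 returns the input exactly, whatever the kind.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding contains non-finite values")
    if spec.magnitude == 0.0:
        return embedding.copy()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "additive-gaussian":
        out = embedding + spec.magnitude * rng.standard_normal(embedding.shape)
    elif spec.kind == "channel-scale":
        out = embedding * (1.0 + spec.magnitude * rng.uniform(-1, 1, embedding.shape))
    else:  # latent-interpolate
        if spec.reference is None:
            raise ValueError("latent-interpolate needs a reference embedding")
        ref = np.asarray(spec.reference, dtype=np.float64)
        if ref.shape != embedding.shape:
            raise ValueError("reference embedding shape mismatch")
        out = (1.0 - spec.magnitude) * embedding + spec.magnitude * ref
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("perturbed embedding is non-finite")
    return out


def synthesize(image: LabeledImage, codec: CodecState,
               specs: list[PerturbSpec]) -> list[LabeledImage]:
    """Generate one synthetic variant per spec (three in the protocol).

    Each output is decode(perturb(encode(image))): same label as the
    source, provenance ``synthetic`` with ``origin_id`` set.
    """
    codec.require_trained()
    s = codec.config.image_size
    if image.pixels.shape[:2] != (s, s):
        raise ValueError(
            f"image {image.id} is {image.pixels.shape[:2]}, codec expects ({s}, {s})"
        )
    emb = encode_full_batch(image.pixels[None], codec)[0]
    perturbed = np.stack([perturb_latent(emb, sp) for sp in specs])
    decoded = decode_full_batch(perturbed, codec)
    return [
        LabeledImage(pixels=decoded[i], label=image.label,
                     id=f"{image.id}-syn{i}", source="synthetic",
                     origin_id=image.id)
        for i in range(len(specs))
    ]


def _specs_for_image(idx: int, emb_all: np.ndarray, labels: np.ndarray,
                     plan: ExpansionPlan) -> list[PerturbSpec]:
    """Three distinct-kind specs for training image ``idx``, seeded by plan."""
    specs = []
    for j, kind in enumerate(PERTURB_KINDS):
        seed = np.random.SeedSequence([plan.seed, idx, j]).generate_state(1)[0]
        ref = None
        if kind == "latent-interpolate":
            same = np.flatnonzero(labels == labels[idx])
            same = same[same != idx]
            pool = same if same.size else np.array([idx])
            rng = np.random.default_rng([plan.seed, idx, 77])
            ref = emb_all[rng.choice(pool)]
        specs.append(PerturbSpec(kind=kind,
                                 magnitude=plan.magnitudes[kind],
                                 seed=int(seed), reference=ref))
    return specs


def generate_synthetics(train: ImageDataset, codec: CodecState,
                        plan: ExpansionPlan) -> ImageDataset:
    """All 3N candidate synthetics (before selection), batched through the codec."""
    codec.require_trained()
    if any(im.source != "real" for im in train):
        raise ValueError("synthesis pool must contain only real images")
    imgs = train.pixel_stack()
    emb_all = encode_full_batch(imgs, codec)
    labels = train.labels
    all_perturbed, meta = [], []
    for i, im in enumerate(train):
        for j, sp in enumerate(_specs_for_image(i, emb_all, labels, plan)):
            all_perturbed.append(perturb_latent(emb_all[i], sp))
            meta.append((im, j))
    decoded = decode_full_batch(np.stack(all_perturbed), codec)
    synths = [
        LabeledImage(pixels=decoded[k], label=im.label,
                     id=f"{im.id}-syn{j}", source="synthetic", origin_id=im.id)
        for k, (im, j) in enumerate(meta)
    ]
    return ImageDataset(synths)


def expand_dataset(train: ImageDataset, codec: CodecState,
                   plan: ExpansionPlan) -> ImageDataset:
    """Return the 100 %-expanded training set: N real + N selected synthetics.

    Generates ``per_image_count``·N candidates, then draws
    ``selection_fraction`` of them uniformly at random without replacement
    (a global draw over all candidates; the label mix of the selection is
    whatever the draw produces).
    """
    n = len(train)
    candidates = generate_synthetics(train, codec, plan)
    n_select = int(round(len(candidates) * plan.selection_fraction))
    rng = np.random.default_rng([plan.seed, 0x5E1])
    chosen = rng.choice(len(candidates), size=n_select, replace=False)
    selected = [candidates[i] for i in sorted(chosen)]
    return ImageDataset(list(train) + selected)
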