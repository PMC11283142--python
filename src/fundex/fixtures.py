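"""Synthetic optic-disc-style image fixtures.

Generates small labeled datasets that mimic square region-of-interest crops
around the optic nerve head: a bright disc on a dark fundus-coloured
background, a concentric brighter cup whose radius relative to the disc (the
cup-to-disc ratio, CDR) carries the class signal — cases draw their CDR from
a higher-mean distribution than controls — plus mild vessel-like line
clutter and additive Gaussian pixel noise.  Everything downstream (codec
training, latent perturbation, classifier evaluation) can therefore be
exercised end to end without any external image data.

Reproducibility: one root seed per dataset; each image derives its own
generator from ``(seed, image_index)``, so pixel content is independent of
generation order.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import ImageDataset, LabeledImage

__all__ = ["FixtureConfig", "generate_fixture", "centroid_crop"]

# base palette (RGB, [0,1]): dark fundus, disc rim, cup, vessel
_BG = np.array([0.10, 0.055, 0.045])
_DISC = np.array([0.85, 0.55, 0.30])
_CUP = np.array([0.97, 0.84, 0.55])
_VESSEL = np.array([0.45, 0.12, 0.10])


@dataclasses.dataclass
class FixtureConfig:
    """Generator settings.

    ``class_balance`` is the fraction of case (label 1) images.  The CDR
    means must satisfy 0 < cdr_negative < cdr_positive < 1 so that cases
    show the larger cup.  ``jitter_px`` bounds the random placement offset
    of the disc centre (0 disables all nuisance randomness except noise).
    """

    n_images: int = 200
    image_size: int = 48
    class_balance: float = 0.5
    cdr_negative: float = 0.35
    cdr_positive: float = 0.65
    cdr_sd: float = 0.08
    noise_sd: float = 0.04
    jitter_px: int = 2
    disc_radius_frac: float = 0.32
    n_vessels: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.cdr_negative < self.cdr_positive < 1.0):
            raise ValueError(
                "CDR ordering must satisfy 0 < cdr_negative < cdr_positive < 1, "
                f"got {self.cdr_negative} / {self.cdr_positive}"
            )
        if self.n_images < 1:
            raise ValueError("n_images must be positive")
        if self.image_size < 8:
            raise ValueError("image_size too small to render a disc")
        if not (0.0 <= self.class_balance <= 1.0):
            raise ValueError("class_balance must lie in [0, 1]")
        if self.noise_sd < 0 or self.cdr_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def _disc_alpha(dist: np.ndarray, radius: float) -> np.ndarray:
    """Anti-aliased coverage of a filled circle (1 px soft edge)."""
    return np.clip(radius - dist + 0.5, 0.0, 1.0)


def _render(cfg: FixtureConfig, cdr: float, rng: np.random.Generator) -> np.ndarray:
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0
    if cfg.jitter_px > 0:
        cy += rng.uniform(-cfg.jitter_px, cfg.jitter_px)
        cx += rng.uniform(-cfg.jitter_px, cfg.jitter_px)
    dist = np.hypot(yy - cy, xx - cx)

    img = np.empty((s, s, 3))
    img[:] = _BG

    # vessel-like clutter: dark lines through the disc centre
    base_angles = np.linspace(0.3, np.pi - 0.3, cfg.n_vessels, endpoint=True)
    for k in range(cfg.n_vessels):
        ang = base_angles[k]
        if cfg.jitter_px > 0:
            ang += rng.uniform(-0.25, 0.25)
        nrm = np.array([np.sin(ang), -np.cos(ang)])
        d_line = np.abs((yy - cy) * nrm[0] + (xx - cx) * nrm[1])
        a = np.clip(1.2 - d_line + 0.5, 0.0, 1.0) * 0.55
        img = img * (1 - a[..., None]) + _VESSEL * a[..., None]

    r_disc = cfg.disc_radius_frac * s
    a_disc = _disc_alpha(dist, r_disc)[..., None]
    img = img * (1 - a_disc) + _DISC * a_disc
    a_cup = _disc_alpha(dist, cdr * r_disc)[..., None]
    img = img * (1 - a_cup) + _CUP * a_cup

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_fixture(config: FixtureConfig) -> ImageDataset:
    """Render a labeled dataset per ``config`` (deterministic in seed)."""
    config.validate()
    n = config.n_images
    n_pos = int(round(config.class_balance * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    order = np.random.default_rng([config.seed, 0xC1A55]).permutation(n)
    labels = labels[order]

    images = []
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        mean = config.cdr_positive if labels[i] == 1 else config.cdr_negative
        cdr = float(np.clip(rng.normal(mean, config.cdr_sd), 0.05, 0.95))
        pixels = _render(config, cdr, rng)
        images.append(LabeledImage(pixels=pixels, label=int(labels[i]),
                                   id=f"img{i:04d}"))
    return ImageDataset(images)


def brightness_centroid(pixels: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of above-background luminance."""
    lum = pixels.mean(axis=2)
    w = lum - lum.min()
    total = w.sum()
    if total <= 0:  # flat image: geometric centre
        h, wd = lum.shape
        return (h - 1) / 2.0, (wd - 1) / 2.0
    yy, xx = np.mgrid[0 : lum.shape[0], 0 : lum.shape[1]]
    return float((yy * w).sum() / total), float((xx * w).sum() / total)


def centroid_crop(image: LabeledImage, side: int) -> LabeledImage:
    """Square crop of ``side`` centred on the brightness centroid.

    Stands in for model-based region-of-interest extraction: on disc-like
    images the luminance centroid falls on the disc, so the crop captures
    the nerve head.  The window is clamped to the image bounds.
    """
    h, w, _ = image.pixels.shape
    if side > min(h, w):
        raise ValueError(f"crop side {side} exceeds image size {(h, w)}")
    cy, cx = brightness_centroid(image.pixels)
    top = int(round(cy)) - side // 2
    left = int(round(cx)) - side // 2
    top = min(max(top, 0), h - side)
    left = min(max(left, 0), w - side)
    return LabeledImage(
        pixels=image.pixels[top : top + side, left : left + side].copy(),
        label=image.label, id=image.id, source=image.source,
        origin_id=image.origin_id,
    )
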