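"""Generate latent-perturbation synthetics and run the expansion protocol.

Every real training image is encoded to its embedding, perturbed three ways
(additive Gaussian noise, per-channel scaling, interpolation toward a
same-class image) and decoded back; one third of the 3N candidates is then
selected at random, doubling the training set.
"""

import numpy as np

from fundex import (CodecConfig, ExpansionPlan, FixtureConfig,
                    generate_fixture, train_codec)
from fundex.augment import expand_dataset
from fundex.codec import reconstruction_mae

train = generate_fixture(FixtureConfig(n_images=24, image_size=48, seed=5,
                                       noise_sd=0.05))
cfg = CodecConfig(image_size=48, seed=3)
codec = train_codec(train, cfg, 1, steps=500, seed=21)
codec = train_codec(train, cfg, 2, steps=300, state=codec, seed=22)

expanded = expand_dataset(train, codec, ExpansionPlan(seed=9))
n_real = len(expanded.real_only())
n_syn = len(expanded.synthetic_only())
print(f"{len(train)} real -> {len(expanded)} total ({n_real} real + {n_syn} synthetic)")

src = {im.id: im for im in train}
dev = np.mean([np.abs(s.pixels - src[s.origin_id].pixels).mean()
               for s in expanded.synthetic_only()])
recon = reconstruction_mae(train, codec)
print(f"synthetic deviation from source {dev:.4f} vs reconstruction error {recon:.4f} "
      f"({dev / recon:.1f}x)")
# deviation above reconstruction error is the added variation; the ratio is
# the knob balancing diversity against fidelity to the source image
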