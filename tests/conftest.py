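import numpy as np
import pytest

from fundex import CodecConfig, FixtureConfig, generate_fixture, train_codec
from fundex.data import ImageDataset


def auc_pairwise_oracle(scores, labels) -> float:
    """Brute-force O(n^2) AUC: fraction of case-control pairs where the case
    outscores the control, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def rank_auc(scores, labels) -> float:
    """Fast midrank AUC (Mann-Whitney), exact under ties."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    r = rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    return (r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@pytest.fixture(scope="session")
def fixture_small():
    """40 images, 24x24: cheap dataset for plumbing tests."""
    return generate_fixture(FixtureConfig(n_images=40, image_size=24, seed=7))


@pytest.fixture(scope="session")
def trained_codec_48():
    """Toy codec trained on 64 fixture images (48x48), with 16 held out.

    Level 1 runs the 500-step recipe on raw patches; Level 2 runs 300 steps
    on the frozen latents.  Shared across tests that need a codec whose
    reconstructions are meaningfully better than chance.
    """
    full = generate_fixture(
        FixtureConfig(n_images=80, image_size=48, seed=5, noise_sd=0.05))
    train = full.subset(range(64))
    heldout = full.subset(range(64, 80))
    cfg = CodecConfig(image_size=48, seed=3)
    state = train_codec(train, cfg, 1, steps=500, seed=21)
    state = train_codec(train, cfg, 2, steps=300, state=state, seed=22)
    return train, heldout, state


@pytest.fixture(scope="session")
def heldout_16(trained_codec_48) -> ImageDataset:
    return trained_codec_48[1]
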