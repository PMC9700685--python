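import numpy as np
import pytest

import noduleseg as ns


@pytest.fixture(scope="session")
def default_net():
    """One default-configuration network shared across structural tests."""
    return ns.build_segmenter(seed=0)


@pytest.fixture()
def toy_pair():
    """Hand-built 8×8 mask pair with |G|=4, |P|=6, |G∩P|=3."""
    gt = np.zeros((8, 8), dtype=np.uint8)
    gt[0, :4] = 1
    pred = np.zeros((8, 8), dtype=np.uint8)
    pred[0, 1:5] = 1
    pred[1, :2] = 1
    assert (int(gt.sum()), int(pred.sum()), int((gt & pred).sum())) == (4, 6, 3)
    return gt, pred


@pytest.fixture(scope="session")
def small_dataset():
    return ns.synth_dataset(12, seed=11)


def random_mask_pairs(n, shape=(16, 16), seed=0, p_fg=0.3):
    """n random binary mask pairs, including empty/full edge cases."""
    rng = np.random.default_rng(seed)
    pairs = [(np.zeros(shape, int), np.zeros(shape, int)),
             (np.ones(shape, int), np.zeros(shape, int)),
             (np.zeros(shape, int), np.ones(shape, int)),
             (np.ones(shape, int), np.ones(shape, int))]
    while len(pairs) < n:
        pairs.append(((rng.random(shape) < p_fg).astype(int),
                      (rng.random(shape) < p_fg).astype(int)))
    return pairs[:n]
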