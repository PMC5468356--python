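import numpy as np
import pytest

import ki67score as k
from ki67score.ndf import NetworkConfig, TrainConfig, train
from ki67score.patching import SplitPlan, build_splits, crop_patches, patches_to_arrays


@pytest.fixture(scope="session")
def separable_patches():
    """~360 high-contrast patches from six synthetic scenes."""
    data = k.generate_dataset(
        6,
        k.SceneSpec(
            image_height=256, image_width=256,
            n_immunopositive=30, n_immunonegative=30,
            nucleus_radius_range=(6, 10),
        ),
        rng_seed=11,
        aps_targets=(30.0, 50.0, 70.0),
    )
    patches = []
    for i, (img, gt) in enumerate(data):
        patches += crop_patches(img, gt.seeds, image_id=f"im{i}")
    return patches


@pytest.fixture(scope="session")
def trained_small_net(separable_patches):
    """A small network trained 100 iterations on separable patches,
    with its held-out validation arrays and history."""
    tr, va = build_splits(separable_patches, SplitPlan(rng_seed=0))
    Xtr, ytr = patches_to_arrays(tr)
    Xva, yva = patches_to_arrays(va)
    net, hist = train(
        Xtr, ytr, NetworkConfig.small(),
        TrainConfig.desk_scale(max_iter=100, rng_seed=0),
        Xva, yva,
    )
    return net, hist, (Xva, yva)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
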