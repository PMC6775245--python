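"""Shared fixtures: synthetic fixture families and the desk-scale trained model."""

import numpy as np
import pytest

from earcount import segnet, synthetic
from earcount.annotations import AugmentParams, PatchSet, augment, split_train_val

#: scene family used for exact-count checks: well-separated, awn-free ellipses
#: on a plain background (no shading), so each instance is one crisp blob
SEPARATED = dict(
    n_ears=8,
    overlap_limit=0.0,
    min_clearance=15,
    awn_probability=0.0,
    illumination_amplitude=0.0,
    n_shadows=0,
    blur_sigma=0.5,
    background_scale=48,
)


def separated_scene(seed: int) -> synthetic.SyntheticScene:
    return synthetic.generate_scene(synthetic.SceneParams(seed=seed, **SEPARATED))


@pytest.fixture(scope="session")
def desk_patchset() -> PatchSet:
    """200 labeled patches (100 ear / 100 background) from seeded scenes."""
    return synthetic.generate_patchset(n_per_class=100, seed=42)


@pytest.fixture(scope="session")
def desk_model(desk_patchset):
    """Desk-scale network trained on the 200-patch set plus one augmented
    copy of each patch; returns (model, history). Shared across tests because
    CPU training dominates the suite's runtime."""
    rng = np.random.default_rng(43)
    extra = [augment(p, AugmentParams(), rng) for p in desk_patchset]
    full = PatchSet(list(desk_patchset) + extra)
    train_set, val_set = split_train_val(full, 0.2, seed=7)
    config = segnet.ModelConfig(input_size=(64, 64, 3), width_multiplier=0.125)
    model = segnet.build_model(config, seed=7)
    model, history = segnet.train(
        model, train_set, val_set,
        segnet.TrainConfig(epochs=10, learning_rate=1e-3, batch_size=8, seed=7),
    )
    return model, history


def flat_color_patchset(n_per_class=5, size=32, seed=11) -> PatchSet:
    """Trivially color-separable patches: crisp gold rectangles on a flat
    green background (ear class) and plain green crops (background class)."""
    from earcount.annotations import BACKGROUND, EAR, Patch

    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n_per_class):
        img = np.zeros((size, size, 3), np.uint8)
        img[...] = (70, 110, 50)
        y0, x0 = rng.integers(2, size // 2, 2)
        h, w = rng.integers(size // 4, size // 2, 2)
        img[y0:y0 + h, x0:x0 + w] = (200, 170, 60)
        mask = (img[..., 0] > 128).astype(np.uint8)
        patches.append(Patch(img, mask, EAR))
    for _ in range(n_per_class):
        img = np.zeros((size, size, 3), np.uint8)
        img[...] = (70, 110, 50)
        patches.append(Patch(img, np.zeros((size, size), np.uint8), BACKGROUND))
    return PatchSet(patches)


@pytest.fixture(scope="session")
def tiny_overfit_model():
    """Small network overfit on 10 trivially separable color patches; sanity
    fixture for inference tests."""
    pset = flat_color_patchset()
    config = segnet.ModelConfig(input_size=(32, 32, 3), width_multiplier=0.125)
    model = segnet.build_model(config, seed=3)
    model, history = segnet.train(
        model, pset, pset,
        segnet.TrainConfig(epochs=50, learning_rate=2e-3, batch_size=4, seed=3),
    )
    return model, history, pset
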