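"""Shared fixtures: synthetic root systems and a toy trained network.

The toy DSResUNet (narrow channels, shallow, small refinement head) is
trained once per session on 20 synthetic image/mask pairs and reused by
every test that needs a working segmentation model.
"""

import numpy as np
import pytest

from chronorsa.segnets import (ArchitectureConfig, TrainingConfig,
                               build_dsresunet, train_model)
from chronorsa.synthetic import (RootSystemSpec, render_image, render_mask,
                                 simulate_root_system)

# toy benchmark conditions (fixed): 20 training pairs, 200 steps
TOY_ARCH = dict(base_feature_maps=8, depth=2, block_type="residual",
                deep_supervision=True, head_width=16)
TOY_TRAIN = dict(learning_rate=3e-3, patch_size=96, batch_size=8,
                 steps=200, rng_seed=0)


def make_pairs(seed0: int, n: int):
    """(image, mask) pairs at assorted growth stages and positions."""
    pairs = []
    for s in range(n):
        spec = RootSystemSpec(
            seed_position=(10, 64 + 10 * (s % 5)), mr_speed=0.2 + 0.01 * s,
            lr_emergence_times=(10.0, 20.0), lr_angles=(50.0, -55.0),
            lr_speeds=(0.12, 0.1), duration_h=40, image_size=(192, 192),
            mm_per_px=0.1, rng_seed=seed0 + s)
        gt = simulate_root_system(spec)
        frame = gt.frames[len(gt.frames) // 2 + 10 * (s % 3)]
        mask = render_mask(frame, spec)
        pairs.append((render_image(mask, spec, 0), mask))
    return pairs


@pytest.fixture(scope="session")
def toy_training():
    """(trained toy DSResUNet, loss history, held-out pairs)."""
    model = build_dsresunet(ArchitectureConfig(**TOY_ARCH))
    model, history = train_model(model, make_pairs(100, 20),
                                 TrainingConfig(**TOY_TRAIN))
    return model, history, make_pairs(900, 5)


@pytest.fixture(scope="session")
def toy_model(toy_training):
    return toy_training[0]


@pytest.fixture()
def two_lr_spec():
    """Root system with two laterals, fully inside a 200x200 plate."""
    return RootSystemSpec(
        seed_position=(10, 100), mr_speed=0.25,
        lr_emergence_times=(10.0, 20.0), lr_angles=(50.0, -45.0),
        lr_speeds=(0.12, 0.1), duration_h=50, image_size=(200, 200),
        mm_per_px=0.1, rng_seed=1)
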