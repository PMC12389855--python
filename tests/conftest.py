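import numpy as np
import pytest

import tacpose as tp
from tacpose._seeding import spawn_seed


@pytest.fixture(scope="session")
def desk_cfg():
    return tp.desk_config(seed=3)


@pytest.fixture(scope="session")
def desk_body():
    return tp.desk_body()


@pytest.fixture(scope="session")
def small_cfg():
    """32x20 raster of the desk mat patch for fast training tests."""
    return tp.desk_config(frame_h=32, frame_w=20, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg, desk_body):
    scenes, split = tp.make_dataset(340, small_cfg, desk_body)
    return scenes, split


@pytest.fixture(scope="session")
def desk_sched():
    return tp.make_schedule(10, 0.999, 0.99)


@pytest.fixture(scope="session")
def small_ucfg():
    return tp.UNetConfig(depth=2, base_channels=16,
                         cda=tp.CDAConfig(channels=8, n_heads=2, pool_size=4))


@pytest.fixture(scope="session")
def trained_stage1(small_dataset, desk_sched, small_ucfg):
    """One trained desk-scale restoration model shared by the heavy tests."""
    scenes, split = small_dataset
    train = [scenes[i] for i in split["train"]]
    model, hist = tp.train_stage1(
        train, desk_sched, tp.MaskParams(threshold=3.0), small_ucfg,
        tp.Stage1TrainConfig(epochs=5, batch=8, seed=0, lr=5e-3),
    )
    return model, hist


@pytest.fixture(scope="session")
def restored_frames(small_dataset, trained_stage1, desk_sched):
    """Restored noisy frames for every scene index used downstream."""
    scenes, _ = small_dataset
    model, _ = trained_stage1

    cache: dict[int, np.ndarray] = {}

    def get(i: int) -> np.ndarray:
        if i not in cache:
            cache[i] = tp.reverse_denoise(
                scenes[i].noisy, desk_sched, tp.MaskParams(threshold=3.0), model,
                rng_seed=spawn_seed(99, "restore", i),
            )
        return cache[i]

    return get
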