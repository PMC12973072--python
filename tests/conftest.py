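import numpy as np
import pytest
from hypothesis import settings

import wormviz as wv

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free, vignette-free two-worm recording with truth."""
    scene = wv.SimScene(
        shape=(64, 64), duration_s=60.0, n_worms=2,
        noise_sigma=0.0, vignette_strength=0.0, seed=7,
    )
    stack, truth = wv.simulate(scene)
    return scene, stack, truth


def random_stack(rng, n=8, rows=16, cols=16, fps=1.0):
    return wv.FrameStack.from_frames(rng.random((n, rows, cols)), fps=fps)
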