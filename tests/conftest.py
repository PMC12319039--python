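import numpy as np
import pytest

from podmatch.synth import SynthConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic occluded scene shared by read-only tests."""
    cfg = SynthConfig(n_pods_range=(12, 18), occlusion_rate=0.3, seed=42)
    front, rear, truth = generate_scene(cfg)
    return cfg, front, rear, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
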