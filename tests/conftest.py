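"""Shared fixtures: small synthetic scenes and fast pipeline configs."""

import numpy as np
import pytest

from barnsense import PipelineConfig, make_samples, build_ensemble, split_kernel_outer
from barnsense.synthetic import SceneSpec, generate


def balanced_zone_map(n_sensors: int = 30, n_zones: int = 3) -> dict:
    """Equal-sized zones laid out in contiguous blocks per layer."""
    per_layer = n_sensors // 2
    block = per_layer // n_zones
    return {f"L-{i + 1}": min((i % per_layer) // block, n_zones - 1)
            for i in range(n_sensors)}


@pytest.fixture(scope="session")
def summer_scene_3z():
    """Two weeks of summer data with three balanced planted zones."""
    spec = SceneSpec(days=14, seed=42, start="2022-06-01 00:00",
                     n_zones=3, zone_map=balanced_zone_map(30, 3))
    env, truth = generate(spec)
    return env, truth


@pytest.fixture(scope="session")
def summer_scene_5z():
    """Two weeks of summer data with the default five column zones."""
    spec = SceneSpec(days=14, seed=7, start="2022-06-01 00:00")
    env, truth = generate(spec)
    return env, truth


@pytest.fixture(scope="session")
def fast_cfg():
    return PipelineConfig(seed=1, ensemble_size=10, pso_max_iter=60,
                          ga_generations=25)


@pytest.fixture(scope="session")
def clustered_inputs(summer_scene_3z, fast_cfg):
    """(samples, stability) for the 3-zone scene, shared across tests."""
    env, _ = summer_scene_3z
    samples = make_samples(env, cfg=fast_cfg)
    stability = split_kernel_outer(samples, build_ensemble(samples, fast_cfg))
    return samples, stability


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
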