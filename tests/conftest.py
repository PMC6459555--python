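import dataclasses

import pytest

from autoflux import masking, pipeline, synth


def synthetic_run_config() -> pipeline.RunConfig:
    """Analysis parameters matched to the synthetic default conditions."""
    return pipeline.RunConfig()


def small_scene_spec(seed: int = 1, **overrides) -> synth.SceneSpec:
    """A fast 8-cell scene for unit tests (~0.5 s to render)."""
    base = synth.SceneSpec(
        field_shape=(16, 224, 224), n_cells=8, edge_margin_vox=26.0, seed=seed
    )
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def default_scene():
    """One full-size default scene, shared across tests (read-only)."""
    spec = synth.SceneSpec(seed=1)
    stacks, truth = synth.generate_scene(spec)
    empty = synth.generate_empty_field(synth.SceneSpec(seed=9001))
    return stacks, truth, empty


@pytest.fixture(scope="session")
def default_pipeline_result(default_scene):
    """Full image pipeline run on the shared default scene."""
    stacks, truth, empty = default_scene
    cfg = synthetic_run_config()
    result = pipeline.run_image_pipeline(cfg, stacks, empty)
    return result, truth


@pytest.fixture(scope="session")
def background_model(default_scene):
    _, _, empty = default_scene
    return masking.fit_background_gaussian(empty)
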