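import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hsiseg import (  # noqa: E402
    SceneSpec,
    apply_pca,
    build_artificial_stack,
    fit_pca,
    generate_scene,
    split_tiles,
    tile_scene,
)


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64x16, 3-class scene shared by read-only tests."""
    spec = SceneSpec(height=64, width=64, n_bands=16, n_classes=3, seed=7)
    cube, labels, members = generate_scene(spec)
    return spec, cube, labels, members


@pytest.fixture(scope="session")
def small_tiles(small_scene):
    """Preprocessed 32-pixel tiles of the small scene, split 8:2."""
    spec, cube, labels, _ = small_scene
    model = fit_pca(cube, k=6)
    pca_cube = apply_pca(cube, model)
    stack = build_artificial_stack(cube, model)
    tiles = tile_scene(pca_cube, stack, labels, tile=32)
    train, test = split_tiles(tiles, ratio=0.75, seed=3)
    return train, test, labels
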