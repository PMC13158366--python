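import numpy as np
import pytest

from mitomorph.synth import SceneSpec, generate_multicell_field, generate_scene


def scene_spec_for_seed(seed: int) -> SceneSpec:
    """Scene with object counts drawn from the study ranges, seeded."""
    rng = np.random.default_rng(seed)
    return SceneSpec(
        rng_seed=seed,
        n_punctates=int(rng.integers(5, 21)),
        n_rods=int(rng.integers(5, 21)),
        n_networks=int(rng.integers(1, 6)),
    )


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic mid-size scene with its ground truth."""
    spec = SceneSpec(rng_seed=0, n_punctates=8, n_rods=8, n_networks=2)
    img, truth = generate_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def multicell_scene():
    """A three-cell field with nuclei channel and ground truth."""
    cell_spec = SceneSpec(
        rng_seed=3, n_punctates=4, n_rods=4, n_networks=1, image_shape=(600, 800)
    )
    mito, nuclei, truth = generate_multicell_field(3, cell_spec, with_nuclei=True)
    return mito, nuclei, truth
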