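import numpy as np
import pytest
from hypothesis import settings

from mitoredox import GeneratorConfig, build_scene, render_stack

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: desk-scale acquisition: same pixel pitch as the default geometry
SMALL = dict(px=128, fov_um=127.0 * 128 / 512, n_slices=6)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        **SMALL, n_neurite_objects=20, n_soma_objects=10, seed=11
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return build_scene(small_config)


@pytest.fixture(scope="session")
def small_stack(small_scene, small_config):
    return render_stack(small_scene, small_config)


@pytest.fixture(scope="session")
def clean_config() -> GeneratorConfig:
    """Noise-free, PSF-free acquisition: the exactly invertible regime."""
    return GeneratorConfig(
        **SMALL,
        n_neurite_objects=20,
        n_soma_objects=10,
        seed=12,
        poisson_noise=False,
        psf_sigma_um=0.0,
    )


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return build_scene(clean_config)


@pytest.fixture(scope="session")
def clean_stack(clean_scene, clean_config):
    return render_stack(clean_scene, clean_config)


def match_to_truth(obj, truth_labels: np.ndarray) -> int:
    """Truth object id with the largest footprint overlap (0 = background)."""
    ids, counts = np.unique(truth_labels[obj.voxels], return_counts=True)
    return int(ids[np.argmax(counts)])
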