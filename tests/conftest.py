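import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import elbowseg as es

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_blobs():
    """Three well-separated 10-point Gaussian blobs with ground truth."""
    pm, labels = es.generate_point_cloud(
        k_true=3, n_per_cluster=10, dim=3, separation=1.0, sigma=0.02, seed=7
    )
    return pm, labels


@pytest.fixture(scope="session")
def default_fixture_image():
    """The standard synthetic benchmark image (4 color populations)."""
    return es.generate_image(es.SyntheticSpec(seed=0))


@pytest.fixture
def png_writer(tmp_path):
    """Write a float [0,1] (H, W, 3) array as an 8-bit PNG, return the path."""
    import imageio.v3 as iio

    def write(arr, name="img.png"):
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
        path = tmp_path / name
        iio.imwrite(path, arr)
        return path

    return write
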