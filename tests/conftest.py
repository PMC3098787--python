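import numpy as np
import pytest

from phenotexture import (
    RunConfig,
    SyntheticDatasetSpec,
    make_texture_dataset,
    run_extract,
    scan_dataset,
    write_dataset,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_dataset():
    """The default easy 5-class synthetic texture dataset (seeded)."""
    spec = SyntheticDatasetSpec()
    images, labels = make_texture_dataset(spec)
    return spec, images, labels


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, easy_dataset):
    _, images, labels = easy_dataset
    root = tmp_path_factory.mktemp("synthetic_tree")
    write_dataset(images, labels, root)
    return root


@pytest.fixture(scope="session")
def combined_table(dataset_dir):
    """GLCM + curvelet(mean, std, entropy) features for the easy dataset."""
    index = scan_dataset(dataset_dir)
    config = RunConfig(blocks=("glcm", "curvelet"), curvelet_stats=("mean", "std", "entropy"))
    return run_extract(index, config)
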