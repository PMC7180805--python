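import numpy as np
import pytest

from gazefusion import pipeline, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset on disk (40 images, shared by tests)."""
    root = tmp_path_factory.mktemp("data")
    manifest = synthetic.gen_dataset(40, root, seed=3)
    return manifest


@pytest.fixture(scope="session")
def small_config(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("artifacts")
    return pipeline.RunConfig(
        images_dir=str(small_dataset["images_dir"]),
        gaze_csv=str(small_dataset["gaze_csv"]),
        labels_csv=str(small_dataset["labels_csv"]),
        out_dir=str(out),
        d4=5,
        train_frac=0.75,
        split_seed=3,
    )
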