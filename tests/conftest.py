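import numpy as np
import pytest

from chalkcam import classifier as clf
from chalkcam.synthetic import GrainSpec, PlateLayout, generate_dataset, generate_grain


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """100-grain synthetic dataset (4 plates x 25, 50% chalky), split 2:1:1."""
    root = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(4, PlateLayout(n_grains=25), root, rng_seed=11)
    return manifest, root


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """Tiny backbone trained briefly on the small dataset; shared by the CAM
    and quantification tests that need a model that has actually learned the
    bright-blob feature."""
    manifest, root = small_dataset
    handle = clf.build_backbone("tiny", seed=5)
    result = clf.train(handle, manifest, clf.TrainConfig(max_epochs=10, rng_seed=5), root=root)
    return result


@pytest.fixture()
def untrained_handle():
    return clf.build_backbone("tiny", seed=3)


def make_chalky_grain(seed: int = 21, chalk_fraction: float = 0.35):
    spec = GrainSpec(chalk_present=True, chalk_fraction=chalk_fraction, rng_seed=seed)
    return generate_grain(spec)


def make_clear_grain(seed: int = 22):
    return generate_grain(GrainSpec(chalk_present=False, rng_seed=seed))
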