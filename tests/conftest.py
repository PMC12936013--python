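import numpy as np
import pytest

from lumbarview import dataset, phantom


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small but complete synthetic cohort shared across unit tests:
    8 patients x 2 images, balanced views, default phantom settings."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    manifest = phantom.generate_cohort(
        n_patients=8,
        images_per_patient=2,
        class_balance=0.5,
        base_spec=phantom.PhantomSpec(),
        seed=21,
        out_dir=out,
    )
    return manifest


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    return dataset.split_by_patient(tiny_cohort, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
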