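import numpy as np
import pytest

from valtrans.screening import filter_positive_images
from valtrans.synthetic_data import (
    GeneratorConfig,
    generate_norms,
    generate_participants,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-group synthetic study: 12 negative + 2 positive images."""
    norms = generate_norms(12, 2, seed=11)
    cfg = GeneratorConfig(n_per_group=6, seed=11, n_images=12, n_positive=2)
    ratings, questionnaires, truth = generate_participants(cfg, norms)
    return {
        "norms": norms,
        "ratings": ratings,
        "questionnaires": questionnaires,
        "truth": truth,
        "cfg": cfg,
    }


@pytest.fixture(scope="session")
def small_negative(small_dataset):
    """The same dataset restricted to analysed (non-positive) images."""
    neg, _ = filter_positive_images(small_dataset["norms"])
    ratings = small_dataset["ratings"]
    return {
        **small_dataset,
        "norms": neg,
        "ratings": ratings[ratings["image_id"].isin(neg["image_id"])].reset_index(
            drop=True
        ),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
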