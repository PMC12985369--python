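import warnings

import numpy as np
import pandas as pd
import pytest

from nichegraph import deconvolution as deconv
from nichegraph import preprocess as pp
from nichegraph import synthetic as syn

warnings.filterwarnings("ignore", message=".*zero size factor.*")


@pytest.fixture(scope="session")
def study_config():
    return syn.default_config(seed=11)


@pytest.fixture(scope="session")
def dataset(study_config):
    """One full synthetic bundle shared by read-only tests."""
    atlas, spots, truth = syn.generate_dataset(study_config)
    return atlas, spots, truth


@pytest.fixture(scope="session")
def atlas_norm(dataset):
    atlas, _, _ = dataset
    norm, kept = pp.normalize_logtp10k(atlas.X)
    vals = pd.DataFrame(
        norm,
        index=np.asarray(atlas.obs_names)[kept],
        columns=list(atlas.var_names),
    )
    return vals, atlas.obs.loc[vals.index]


@pytest.fixture(scope="session")
def weights(dataset, study_config):
    _, spots, _ = dataset
    profiles = syn.base_profiles(study_config)
    return deconv.decompose(spots, profiles)
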