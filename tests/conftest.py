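import numpy as np
import pytest

import dimlight as dl


@pytest.fixture(scope="session")
def jtt():
    return dl.build_model("JTT")


@pytest.fixture(scope="session")
def gamma4():
    return dl.discrete_gamma(0.93, 4)


@pytest.fixture
def quartet_tree():
    return dl.read_newick("((A:0.2,B:0.3):0.15,C:0.25,D:0.4);")


@pytest.fixture
def noiseless():
    return dl.NoiseModel(
        assay_sd={a: 0.0 for a in dl.io.ASSAYS}, spectral_sd=0.0, seed=1
    )


def make_alignment(tree, model, rates, n_sites, seed):
    return dl.gen_alignment(tree, dl.EvolModel(model, rates), n_sites, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
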