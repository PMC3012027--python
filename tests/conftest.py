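import numpy as np
import pytest

from mcbpps.preprocess import compute_weights
from mcbpps.sampler import McBppsSampler, SamplerConfig
from mcbpps.synthetic import generate, standard_fixture_spec


@pytest.fixture(scope="session")
def small_fixture():
    """3 subgroups x 30 sequences + 10 decoys, 120 columns — fast."""
    spec = standard_fixture_spec(
        rng_seed=7, seqs_per_subgroup=30, n_decoys=10, length=120
    )
    msa, seeds, truth = generate(spec)
    return spec, compute_weights(msa), seeds, truth


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard recovery fixture: 3 x 100 sequences + 30 decoys."""
    spec = standard_fixture_spec(rng_seed=1)
    msa, seeds, truth = generate(spec)
    return spec, compute_weights(msa), seeds, truth


@pytest.fixture(scope="session")
def converged_small(small_fixture):
    spec, msa, seeds, truth = small_fixture
    sampler = McBppsSampler(
        msa, spec.hyperpartition, seeds, config=SamplerConfig(rng_seed=7)
    )
    state, trace = sampler.run()
    return sampler, state, trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
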