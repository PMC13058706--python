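import numpy as np
import pytest

import mifquant as mq

SMALL_COUNTS = {"b_cell": 40, "plasma_cell": 30, "bona_fide_pb": 5, "t_nk_like": 8}


def small_spec(seed=7, **overrides):
    kwargs = dict(
        image_shape=(512, 512),
        phenotype_counts=dict(SMALL_COUNTS),
        n_tubules=1,
        n_af_artifacts=2,
        noise_sd=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return mq.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def phantom_small():
    """Noiseless 512px tile with all object classes planted."""
    return mq.generate_phantom(small_spec())


@pytest.fixture(scope="session")
def pipeline_small(phantom_small):
    """Full pipeline run on the small noiseless phantom."""
    stack, truth = phantom_small
    result = mq.run_slide(mq.RunConfig(), stack, "s1")
    return stack, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
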