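import numpy as np
import pytest

from nbvoi import BetaPosterior, Threshold, gusto_like_fixture


@pytest.fixture(scope="session")
def thr02():
    return Threshold(0.02)


@pytest.fixture(scope="session")
def case_posterior():
    """Posterior from the 500-record pilot sample with flat priors."""
    return BetaPosterior(prev=(44, 458), sens=(42, 3), spec=(148, 311))


@pytest.fixture(scope="session")
def pilot_sample():
    return gusto_like_fixture()


@pytest.fixture(scope="session")
def case_draws_factory(case_posterior):
    """Factory for posterior-draw matrices sampled from the case posteriors."""

    def make(m, seed):
        rng = np.random.default_rng(seed)
        p, se, sp = case_posterior.sample(rng, m)
        return np.column_stack([p, se, sp])

    return make
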