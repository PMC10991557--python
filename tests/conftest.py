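import numpy as np
import pytest
from hypothesis import settings

import isoniche as iso

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def community():
    """The packaged 63-sample, five-species synthetic community."""
    return iso.default_community(7)


@pytest.fixture(scope="session")
def filtered(community):
    return iso.complete_case_filter(community)


@pytest.fixture(scope="session")
def space_5d(filtered):
    space, pca_c, pca_n = iso.build_dimension_space(filtered, "5D")
    return space


@pytest.fixture(scope="session")
def two_group_posteriors():
    """Posteriors for two well-separated 2-D normal samples."""
    rng = np.random.default_rng(42)
    a = rng.multivariate_normal([0, 0], np.eye(2), size=40)
    b = rng.multivariate_normal([3, 0], [[1.0, 0.3], [0.3, 0.8]], size=40)
    post_a = iso.sample_posterior(a, K=2000, seed=1, group="a")
    post_b = iso.sample_posterior(b, K=2000, seed=2, group="b")
    return post_a, post_b
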