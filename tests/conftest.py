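import numpy as np
import pytest

from hfrpam.factor_model import ExpertPanel, default_hierarchy


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def make_panel(hierarchy):
    """Build an ExpertPanel from a 2-D list/array of ratings."""

    def _make(ratings):
        r = np.asarray(ratings, dtype=np.int64)
        return ExpertPanel(
            ratings=r,
            factor_codes=hierarchy.factors,
            expert_ids=tuple(str(i) for i in range(1, r.shape[0] + 1)),
        )

    return _make


@pytest.fixture
def random_panel(make_panel):
    """Uniform-random integer panel of a given shape and seed."""

    def _make(n_experts, seed):
        rng = np.random.default_rng(seed)
        return make_panel(rng.integers(1, 6, size=(n_experts, 8)))

    return _make
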