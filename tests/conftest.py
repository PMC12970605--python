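import numpy as np
import pytest

from otalign.core import ObjectiveConfig, fit, hyperparameter_search
from otalign.io import DataMatrix, zscore
from otalign.simulate import make_pair, sample_synthetic_counts

# Scaled-down study conditions used by the heavier end-to-end tests:
# 300 cells per domain lifted to 100 features, a 4-point hyperparameter
# grid obeying lambda_ortho > lambda_topo, and a capped epoch budget.
SEARCH_GRID = {
    "lambda_ortho": [1e-1, 1e-2],
    "lambda_topo": [1e-3],
    "reach": [None],
}
FIT_EPOCHS = 200


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on
    # which other tests ran before
    return np.random.default_rng(0)


def run_search(design: str, seed: int = 1):
    pair = make_pair(design, n=300, target_dim=100, seed=seed)
    base = ObjectiveConfig(max_epochs=FIT_EPOCHS, seed=0)
    model, table = hyperparameter_search(
        pair.domain_x, pair.domain_y, grids=SEARCH_GRID, base_config=base
    )
    return pair, model, table


@pytest.fixture(scope="session")
def branch_search():
    """Unsupervised grid-selected model on the branch design (shared by
    the alignment, co-clustering and evaluation tests)."""
    return run_search("branch")


@pytest.fixture(scope="session")
def design_searches(branch_search):
    """Grid-selected models for all three manifold designs."""
    return {
        "branch": branch_search,
        "swiss_roll": run_search("swiss_roll"),
        "circular_frustum": run_search("circular_frustum"),
    }


@pytest.fixture(scope="session")
def counts_fit():
    """Alignment of a 3-group count-valued pair (discrete cell types),
    used by the co-clustering tests."""
    pair = sample_synthetic_counts(n=300, d=50, n_groups=3, seed=2)
    x = DataMatrix(zscore(np.log1p(pair.domain_x.values)), labels=pair.domain_x.labels)
    y = DataMatrix(zscore(np.log1p(pair.domain_y.values)), labels=pair.domain_y.labels)
    model = fit(x, y, ObjectiveConfig(max_epochs=200, seed=0))
    return pair, x, y, model


@pytest.fixture(scope="session")
def small_fit():
    """A quick single-config fit on a small branch pair for tests that
    need any trained model."""
    pair = make_pair("branch", n=120, target_dim=40, seed=3)
    cfg = ObjectiveConfig(max_epochs=120, seed=0, init_align="fast")
    model = fit(pair.domain_x, pair.domain_y, cfg)
    return pair, model
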