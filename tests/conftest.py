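import numpy as np
import pandas as pd
import pytest

from bmhet.models import ModelSpec
from bmhet.simulate import (
    draw_generating_params,
    sim_mvbm,
    sim_pure_birth,
    sim_regime_history,
)


def random_painted(n_taxa, n_regimes, seed, rate=None, min_tips=1):
    """A random Yule tree with a random Mk regime painting."""
    rng = np.random.default_rng(seed)
    tree = sim_pure_birth(n_taxa, seed=rng)
    return sim_regime_history(
        tree, n_regimes, rate=rate, min_tips=min_tips, seed=rng
    )


def random_dataset(n_taxa, n_regimes, code, seed, min_tips=1):
    """(painted tree, generating spec, rates, trait table) for one draw."""
    rng = np.random.default_rng(seed)
    tree = sim_pure_birth(n_taxa, seed=rng)
    painted = sim_regime_history(tree, n_regimes, min_tips=min_tips, seed=rng)
    spec = ModelSpec(code, tuple(painted.regimes))
    rates = draw_generating_params(spec, rng)
    traits = sim_mvbm(painted, rates, seed=rng)
    return painted, spec, rates, traits


@pytest.fixture
def cherry_traits():
    """Two tips diverging at the root, unit branches, all-zero traits."""
    from bmhet.trees import parse_simmap

    tree = parse_simmap("(A:{0,1.0},B:{0,1.0});")
    x = pd.DataFrame({"x1": [0.0, 0.0], "x2": [0.0, 0.0]}, index=["A", "B"])
    return tree, x
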