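import numpy as np
import pytest
from hypothesis import settings

import hostislands as hi

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def tree3():
    """((A:1,B:1):1,C:2); — the 3-tip hand-oracle tree."""
    return hi.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    """((A:1,B:1):1,(C:1,D:1):1); — two cherries, hand-computable Σd."""
    return hi.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def yule200():
    return hi.simulate_tree(200, seed=101)


@pytest.fixture(scope="session")
def apparency420():
    """Synthetic study-scale apparency table (420 families)."""
    return hi.simulate_apparency(420, seed=3)


@pytest.fixture(scope="session")
def species420(apparency420):
    return np.array([r.n_species for r in apparency420])


@pytest.fixture
def synth_dataset(tmp_path):
    """Small full synthetic study on disk (tree + tables).

    Group parameters keep expected prevalence comfortably above the
    10-host-family retention floor at n = 80.
    """
    groups = [
        hi.GroupSpec("logi_a", "logistic", {"a": 0.002, "b": -1.0}),
        hi.GroupSpec("logi_b", "logistic", {"a": 0.004, "b": -1.5}),
        hi.GroupSpec("clump_a", "clumped", {"k": 16}),
        hi.GroupSpec("clump_b", "clumped", {"k": 28}),
        hi.GroupSpec("rand_a", "random", {"p": 0.25}),
        hi.GroupSpec("rand_b", "random", {"p": 0.4}),
    ]
    config = hi.SimulationConfig(n_families=80, seed=7, groups=groups)
    meta = hi.simulate_dataset(config, tmp_path / "data")
    return tmp_path / "data", meta
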