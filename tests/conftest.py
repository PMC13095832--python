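import numpy as np
import pytest

import cutevo as cv
from cutevo.synthetic_data import scenario_tip_vectors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return cv.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def trait_table():
    return cv.load_trait_table()


@pytest.fixture(scope="session")
def study():
    """The frozen study scenario with its tip vectors and fitted model."""
    scenario = cv.study_scenario()
    vectors = scenario_tip_vectors(scenario)
    fit = cv.fit_er_rate(scenario.tree, vectors, scenario.state_labels)
    model = cv.MkModel(scenario.state_labels, fit.q_hat)
    return scenario, vectors, fit, model


@pytest.fixture(scope="session")
def ten_tip_instance():
    """Small fixed instance used for distributional map checks."""
    rng = np.random.default_rng(777)
    tree = cv.simulate_bd_tree(10, 1.0, 0.2, rng, scale_root_age=1.0)
    k = 3
    labels = ("dicot", "grass", "dicot_grass")
    vectors = {}
    for i, tip in enumerate(tree.tips()):
        v = np.zeros(k)
        v[i % k] = 1.0
        vectors[tip.label] = v
    model = cv.MkModel(labels, 0.8)
    return tree, vectors, model
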