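import numpy as np
import pytest

from stgtsim import (
    WorldModel,
    build_split_cs_task,
    build_standard_task,
    update_reward,
    update_transition,
)


@pytest.fixture(scope="session")
def standard_food():
    return build_standard_task("food")


@pytest.fixture(scope="session")
def standard_magazine():
    return build_standard_task("magazine")


@pytest.fixture(scope="session")
def split_graph():
    return build_split_cs_task("magazine")


def make_ideal_model(graph) -> WorldModel:
    """World model with every transition fully learned (T = 1) and the
    terminal reward fully learned (R = 1), all other rewards 0."""
    model = WorldModel()
    for s, a in graph.state_action_pairs():
        nxt = graph.next_state(s, a)
        if nxt is not None:
            update_transition(model, s, a, nxt, alpha=1.0)
        update_reward(model, s, a, graph.reward(s, a), alpha=1.0)
    return model


@pytest.fixture(scope="session")
def ideal_model(standard_food):
    return make_ideal_model(standard_food)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
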