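import numpy as np
import pandas as pd
import pytest

from riveredith.hydrology import extrapolate_hydraulics
from riveredith.network import (RiverNetwork, accumulate_drainage_area,
                                build_network)
from riveredith.synthetic import (ScenarioConfig, make_scenario,
                                  true_hydraulic_laws)


def load_uniform_hydraulics(net: RiverNetwork, *, width=2.0, depth=0.5,
                            discharge=1.0, velocity=None) -> RiverNetwork:
    """Hand-set constant hydraulics on every reach (tests only)."""
    accumulate_drainage_area(net)
    for r in net:
        r.width = width
        r.depth = depth
        r.discharge = discharge
        r.velocity = discharge / (width * depth) if velocity is None else velocity
    return net


def random_tree_records(n_reaches: int, rng: np.random.Generator):
    """Random single-outlet tree edge records: reach k drains into a random
    earlier reach (reach 0 is the outlet)."""
    records = [("r0", None, float(rng.uniform(200, 1500)),
                float(rng.uniform(0.1, 2.0)))]
    for k in range(1, n_reaches):
        down = f"r{int(rng.integers(k))}"
        records.append((f"r{k}", down, float(rng.uniform(200, 1500)),
                        float(rng.uniform(0.1, 2.0))))
    return records


def random_hydraulic_network(n_reaches: int, seed: int) -> RiverNetwork:
    """A random tree with power-law hydraulics loaded (spring)."""
    rng = np.random.default_rng(seed)
    net = build_network(random_tree_records(n_reaches, rng))
    accumulate_drainage_area(net)
    return extrapolate_hydraulics(net, true_hydraulic_laws(["spring"]), "spring")


@pytest.fixture
def y_network() -> RiverNetwork:
    """Two headwaters meeting at a confluence reach (the outlet)."""
    return build_network([
        ("h1", "c", 1000.0, 0.3),
        ("h2", "c", 800.0, 0.4),
        ("c", None, 500.0, 0.5),
    ])


@pytest.fixture
def chain_network() -> RiverNetwork:
    """a → b → c, simple series."""
    return build_network([
        ("a", "b", 1000.0, 0.3),
        ("b", "c", 1000.0, 0.4),
        ("c", None, 1000.0, 0.5),
    ])


@pytest.fixture(scope="session")
def scenario():
    """The default small synthetic study (shared, read-only)."""
    return make_scenario(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def presence_tables(scenario):
    return scenario.true_presence
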