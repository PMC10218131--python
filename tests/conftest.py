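import numpy as np
import pytest

from mobilize_net import GameParameters, GeneratorConfig, TypedNetwork, generate_network


@pytest.fixture
def base_params() -> GameParameters:
    """The reference parameter set of the simulation study (no intervention)."""
    return GameParameters(
        pi_e=8, c_e=2, pi_g=3, c_g=5, c_v=1, c_s=2, beta=0.3, gamma=0, delta=0
    )


@pytest.fixture
def default_network() -> TypedNetwork:
    """A fixed 19-GRS / 49-SRS generated network."""
    return generate_network(GeneratorConfig(seed=0))


@pytest.fixture
def tiny_pair() -> TypedNetwork:
    """One SRS linked to one GRS."""
    return TypedNetwork([("s1", "SRS"), ("g1", "GRS")], [("s1", "g1")])


def random_params(rng: np.random.Generator) -> GameParameters:
    """Random valid parameter draw for property tests."""
    pi_e = rng.uniform(1, 10)
    return GameParameters(
        pi_e=pi_e,
        c_e=rng.uniform(0, pi_e * 0.99),
        pi_g=rng.uniform(0.1, 10),
        c_g=rng.uniform(0.1, 10),
        c_v=rng.uniform(0.1, 5),
        c_s=rng.uniform(0.1, 5),
        beta=rng.uniform(0, 1),
        gamma=rng.uniform(0, 4),
        delta=rng.uniform(0, 4),
    )
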