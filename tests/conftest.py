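import pytest

from tdshaping import ChainSpec, PotentialFunction, build_chain, perfect_shaping


@pytest.fixture(scope="session")
def fig1_problem():
    """The branching chain: p = 0.3, T = 10, unit reward on arrival at s10."""
    return build_chain(ChainSpec(p=0.3, T=10, reward_schedule={10: 1.0}))


@pytest.fixture(scope="session")
def zero_phi(fig1_problem):
    return PotentialFunction.zeros(fig1_problem.n_states)


@pytest.fixture(scope="session")
def ideal_phi():
    """Perfect potential for the T = 10 chain: 1 on s1..s9, 0 at s0 and s10."""
    return perfect_shaping(10)
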