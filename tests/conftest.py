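import pytest

from ipftsp import solve_ipftsp
from ipftsp.synthetic import GeneratorConfig, generate, mnnr_skeleton


def small_config(seed: int, **kwargs) -> GeneratorConfig:
    """A 2-lake, 2-scenario configuration small enough for the oracle."""
    defaults = dict(
        seed=seed,
        n_lakes=2,
        n_intakes=1,
        n_scenarios=2,
        probabilities=(0.6, 0.4),
        flood_fracs=(0.25, 0.5),
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_instance():
    return generate(small_config(seed=1))


@pytest.fixture(scope="session")
def small_solution(small_instance):
    return solve_ipftsp(small_instance)


@pytest.fixture(scope="session")
def default_instance():
    return generate(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_solution(default_instance):
    return solve_ipftsp(default_instance)


@pytest.fixture(scope="session")
def mnnr():
    return mnnr_skeleton()
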