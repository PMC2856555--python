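import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def example_ladder():
    """The worked four-rung ladder whose index is 700/2050 by hand summation."""
    from strindex import RepeatLadder

    return RepeatLadder(111, {0: 1000.0, 1: 500.0, 2: 250.0, -1: 300.0})


@pytest.fixture(scope="session")
def small_expression():
    """A small planted-signature expression draw shared across model tests."""
    from strindex import ExpressionSimParams, simulate_expression

    params = ExpressionSimParams(
        n_tissues=8, n_probes=400, n_signature_probes=20, n_replicates=2,
        effect_size=0.6, noise_sd=0.4, seed=7,
    )
    true_index = {f"t{i}": v for i, v in enumerate(
        np.linspace(-1.0, 6.4, params.n_tissues))}
    expr, truth = simulate_expression(params, true_index)
    return expr, truth
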