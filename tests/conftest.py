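import numpy as np
import pytest
from hypothesis import settings

import twiner as tw

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_dataset(seed: int, n: int = 40, p: int = 6, beta=None) -> tw.ExpressionDataset:
    """Standardized Gaussian design with a logistic outcome."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.5, -1.0, 0.8][: min(3, p)]
    eta = X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # force both classes
        y[0] = 1 - y[0]
    return tw.ExpressionDataset(
        X, [f"s{i}" for i in range(n)], [f"g{j}" for j in range(p)], y
    )


@pytest.fixture(scope="session")
def small_dataset() -> tw.ExpressionDataset:
    return make_dataset(seed=0, n=60, p=8)


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted twin scenario, generated once per session."""
    scenario = tw.TwinScenario(seed=1)
    ds_a, ds_b, truth = tw.generate(scenario)
    return scenario, ds_a, ds_b, truth


@pytest.fixture(scope="session")
def tiny_scenario():
    """A scaled-down scenario for fast protocol tests."""
    scenario = tw.TwinScenario(
        n_a=80,
        n_b=80,
        p=60,
        twin_block=tuple(range(0, 10)),
        specific_blocks=(tuple(range(10, 20)), tuple(range(20, 30))),
        signal_genes=tuple(range(0, 3)),
        seed=11,
    )
    ds_a, ds_b, truth = tw.generate(scenario)
    return scenario, ds_a, ds_b, truth
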