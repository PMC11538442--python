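import numpy as np
import pytest

from causalweb import UniformSeries


def logistic_map(r: float, n: int, x0: float = 0.4) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for t in range(n - 1):
        x[t + 1] = r * x[t] * (1.0 - x[t])
    return x


def coupled_logistic_pair(n: int, coupling: float, seed: int = 0,
                          rx: float = 3.8, ry: float = 3.6):
    """X drives Y unidirectionally with the given coupling strength."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = rng.uniform(0.2, 0.8, 2)
    for t in range(n - 1):
        x[t + 1] = x[t] * (rx - rx * x[t])
        y[t + 1] = y[t] * (ry - ry * y[t] - coupling * x[t])
        x[t + 1] = min(max(x[t + 1], 1e-9), 1.0)
        y[t + 1] = min(max(y[t + 1], 1e-9), 1.0)
    return (UniformSeries(x, name="X"), UniformSeries(y, name="Y"))


@pytest.fixture
def chaotic_series():
    return UniformSeries(logistic_map(3.8, 500), name="logistic")
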