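import numpy as np
import pytest

from valvedim.synthetic import default_truth, generate_population


@pytest.fixture(scope="session")
def population():
    """One default synthetic population, with landmark sets."""
    return generate_population(default_truth(seed=42))


@pytest.fixture(scope="session")
def fast_population():
    """Measurement table only (no landmarks), same conditions."""
    return generate_population(default_truth(seed=7), landmarks=False)


def ellipse_points(a, b, theta=0.0, n=100, center=(0.0, 0.0), noise=0.0,
                   seed=0):
    """Points on (or near) an ellipse with semi-axes a, b."""
    rng = np.random.default_rng(seed)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(ang)
    y = b * np.sin(ang)
    if noise:
        x = x + rng.normal(0, noise, n)
        y = y + rng.normal(0, noise, n)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return np.column_stack([x, y]) @ rot.T + np.asarray(center)
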