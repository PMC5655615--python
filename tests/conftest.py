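import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qsarchance as qc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return qc.make_stream(12345)


@pytest.fixture
def noise_table_21x10():
    """Pure-noise 21-compound table with a 10-descriptor pool."""
    return qc.make_regression_fixture(qc.FixtureSpec(n=21, p=10, seed=11))


@pytest.fixture
def signal_table_21x10():
    """21 compounds, 10 descriptors, one planted signal, population R² = 0.9."""
    spec = qc.FixtureSpec(
        n=21, p=10, signal_descriptors=(0,), beta=(3.0,), noise_sd=1.0, seed=1
    )
    t = qc.make_regression_fixture(spec)
    assert abs(t.metadata["population_r2"] - 0.9) < 1e-12
    return t


@pytest.fixture
def toy_sdf_path(tmp_path):
    p = tmp_path / "toy.sdf"
    p.write_text(qc.make_toy_sdf(4, ["LOGK", "D1", "D2"], seed=5), newline="")
    return p


def naive_q2_loo(X, y):
    """Independent leave-one-out oracle: refit OLS per held-out point."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    press = 0.0
    for i in range(n):
        m = np.ones(n, bool)
        m[i] = False
        Z = np.column_stack([np.ones(n - 1), X[m]])
        b = np.linalg.lstsq(Z, y[m], rcond=None)[0]
        press += (y[i] - (b[0] + X[i] @ b[1:])) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)
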