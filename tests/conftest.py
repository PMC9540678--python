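import numpy as np
import pytest

from labelsurv import Cohort, default_config, make_replicate


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def replicate1(config):
    """One scenario-1 study replicate, shared across read-only tests."""
    return make_replicate(1, config, seed=20240)


@pytest.fixture()
def toy_cohort():
    """Tiny labeled cohort with survival outcomes (deterministic)."""
    rng = np.random.default_rng(7)
    n = 60
    labels = rng.integers(1, 4, size=n)
    x = np.column_stack([labels + rng.normal(0, 0.5, n), rng.normal(0, 1, n)])
    time = rng.exponential(60, n)
    event = time <= 100
    return Cohort(
        features=x,
        labels=labels,
        time=np.minimum(time, 100),
        event=event,
        n_classes=3,
    )
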