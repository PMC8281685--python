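import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from irgpsig import SimulationConfig, simulate_cohort

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def toy_expr():
    """3 genes x 2 samples; S1 strictly decreasing, S2 strictly increasing."""
    return pd.DataFrame(
        [[5.0, 1.0], [3.0, 2.0], [1.0, 3.0]],
        index=pd.Index(["A", "B", "C"], name="gene"),
        columns=["S1", "S2"],
    )


@pytest.fixture(scope="session")
def cohort():
    """Reference synthetic cohort with the default implanted signal."""
    cfg = SimulationConfig(seed=7)
    expr, surv, truth = simulate_cohort(cfg)
    return expr, surv, truth


@pytest.fixture
def toy_surv():
    rng = np.random.default_rng(42)
    n = 60
    time = rng.exponential(100.0, size=n).round(3)
    event = rng.binomial(1, 0.7, size=n)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index([f"S{i}" for i in range(n)], name="sample"),
    )
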