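import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from codaltsa.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across tests (seed fixed)."""
    cfg = GeneratorConfig(n_workers=200)
    return cfg, generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    from codaltsa.pipeline import analyze_frames

    _, cohort = small_cohort
    return analyze_frames(
        cohort.days, cohort.bed, cohort.covariates, cohort.register
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_survival_frame(rng, n=120, p=3, beta=None, weekly=True):
    """Shared helper: random proportional-hazards data with weekly ties."""
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    t = -np.log(rng.random(n)) / (0.02 * np.exp(X @ beta))
    if weekly:
        t = np.ceil(t)
        c = rng.integers(1, 120, n).astype(float)
    else:
        c = rng.uniform(1.0, 120.0, n)
    time = np.minimum(t, c)
    event = t <= c
    Xdf = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    y = pd.DataFrame({"time_weeks": time, "event": event})
    return Xdf, y
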