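import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from samplesim import GeneratorConfig, Population, generate_population

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_pop() -> Population:
    """The default 89-hospital synthetic population, seed 1."""
    return generate_population(GeneratorConfig(), seed=1)


def build_population(rows, regions=None) -> Population:
    """Hand-build a population from (id, type, region, beds, rbc, ffp, plt)."""
    df = pd.DataFrame(
        rows, columns=["hospital_id", "type", "region", "beds", "rbc", "ffp", "plt"]
    )
    return Population(df, regions=regions)


def uniform_stratum(type_, region, n, rbc=None, beds=None, prefix=None):
    """Rows for one stratum with simple deterministic covariates."""
    prefix = prefix or type_[0].upper()
    rows = []
    for i in range(n):
        b = beds[i] if beds is not None else 100 + 10 * i
        r = rbc[i] if rbc is not None else 1000 + 100 * i
        reg = region[i] if isinstance(region, (list, tuple)) else region
        rows.append((f"{prefix}{i + 1:02d}", type_, reg, b, r, r // 4, r // 3))
    return rows


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
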