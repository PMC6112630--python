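import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pubmr.presets import menarche_preset, validation_preset
from pubmr.simulate import simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def menarche():
    return menarche_preset()


@pytest.fixture(scope="session")
def validation():
    return validation_preset()


@pytest.fixture(scope="session")
def menarche_cohort(menarche):
    """One mid-sized draw of the cohort-scale scenario, shared across tests."""
    geno, cohort = simulate_cohort(4000, menarche.snps, menarche.params.replace(seed=7))
    return geno, cohort


@pytest.fixture(scope="session")
def big_menarche_cohort(menarche):
    """A 50k draw for ground-truth-recovery checks."""
    geno, cohort = simulate_cohort(50_000, menarche.snps, menarche.params.replace(seed=13))
    return geno, cohort


def random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small arbitrary dataset with instrument/exposure/outcome columns."""
    z = rng.binomial(2, 0.4, n).astype(float)
    x = 0.6 * z + rng.normal(0, 1, n)
    y = 0.8 * x + rng.normal(0, 1, n)
    return pd.DataFrame({"z": z, "x": x, "y": y})
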