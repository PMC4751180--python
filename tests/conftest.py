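import numpy as np
import pandas as pd
import pytest

from curegwas import SimDesign, resolve_effects, simulate_cohort


def make_toy_cohort(genotype, obs_time, event):
    """Minimal observed-columns cohort for estimator tests."""
    genotype = np.asarray(genotype, dtype=float)
    obs_time = np.asarray(obs_time, dtype=float)
    event = np.asarray(event, dtype=bool)
    return pd.DataFrame(
        {
            "id": np.arange(genotype.size),
            "genotype": genotype,
            "obs_time": obs_time,
            "event": event,
        }
    )


@pytest.fixture(scope="session")
def null_design():
    """Cure fraction 0.5, no genetic effects, default cohort size."""
    return SimDesign(cure_fraction=0.5)


@pytest.fixture(scope="session")
def effect_design():
    """1% SNP heritability on both components, no background, cure 0.5."""
    return SimDesign(
        cure_fraction=0.5, h2_snp_logistic=0.01, h2_snp_survival=0.01
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_design):
    return simulate_cohort(effect_design, resolve_effects(effect_design), seed=12345)


@pytest.fixture(scope="session")
def null_cohort(null_design):
    return simulate_cohort(null_design, resolve_effects(null_design), seed=54321)
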