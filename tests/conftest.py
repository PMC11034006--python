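import numpy as np
import pandas as pd
import pytest

from pwcgen import (
    ClassifierConfig,
    DatasetSpec,
    EffectSpec,
    generate_cohort,
)
from pwcgen.connectome import stack_profiles

# Small, deterministic search space used throughout the suite wherever the
# grid itself is not the thing under test.
FAST_CLF = ClassifierConfig(
    kernels=("rbf",),
    C_grid=(0.1, 1.0, 10.0),
    gamma_grid=("scale",),
    outer_folds=5,
    repeats=1,
    inner_folds=3,
    seed=0,
)


@pytest.fixture
def fast_clf() -> ClassifierConfig:
    return FAST_CLF


def make_cohort(
    n=80,
    n_parcels=12,
    signal=(1, 5, 9),
    delta=0.6,
    noise_sd=0.5,
    age_range=(20.0, 60.0),
    seed=0,
    **dataset_kwargs,
):
    """Convenience wrapper: one cohort plus stacked profiles."""
    spec = DatasetSpec(
        "ds", n, age_range, noise_sd=noise_sd, **dataset_kwargs
    )
    effects = EffectSpec(
        n_parcels=n_parcels, signal_parcels=tuple(signal), sex_effect_size=delta
    )
    demo, conn = generate_cohort(spec, effects, seed)
    return demo, conn, stack_profiles(conn), effects


@pytest.fixture
def signal_cohort():
    return make_cohort()


@pytest.fixture
def null_cohort():
    return make_cohort(delta=0.0, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
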