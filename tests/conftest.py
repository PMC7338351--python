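import numpy as np
import pytest

from epiboost.engine import HyperParams
from epiboost.synthetic import (
    DemographicSpec,
    EffectTerm,
    SyntheticSpec,
    generate_cohort,
)

#: fast, fixed hyperparameters for simulation-scale fits (inside the
#: published search ranges)
FAST_PARAMS = HyperParams(
    n_trees=50,
    tree_depth=4,
    learning_rate=0.1,
    subsample_rate=0.8,
    min_child_weight=1.0,
    gamma=0.0,
    alpha=1e-5,
    scale_pos_weight=1.0,
)


@pytest.fixture(scope="session")
def fast_params() -> HyperParams:
    return FAST_PARAMS


def informative_spec(seed: int = 11, n_subjects: int = 500, n_snps: int = 30) -> SyntheticSpec:
    """A small cohort with one common causal SNP and one causal demographic."""
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_snps=n_snps,
        demographics=[
            DemographicSpec("smoker", "categorical", "group1", probs=(0.6, 0.4)),
            DemographicSpec("parity", "categorical", "group1", probs=(0.3, 0.4, 0.3)),
            DemographicSpec("bmi", "continuous", "group2", mean=26.0, std=4.5),
        ],
        effects=[
            EffectTerm("main_snp", ("snp00001",), 1.2),
            EffectTerm("main_demog", ("smoker",), 0.9),
        ],
        maf_overrides={"snp00001": 0.3},
        seed=seed,
    )


@pytest.fixture(scope="session")
def informative_cohort():
    cohort, truth = generate_cohort(informative_spec())
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No effects at all: labels independent of every feature."""
    spec = SyntheticSpec(
        n_subjects=300,
        n_snps=20,
        demographics=[
            DemographicSpec("smoker", "categorical", "group1", probs=(0.6, 0.4)),
            DemographicSpec("bmi", "continuous", "group2", mean=26.0, std=4.5),
        ],
        seed=21,
    )
    cohort, truth = generate_cohort(spec)
    return cohort, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
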