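import numpy as np
import pytest

from indelcal import (
    PointScale,
    ScoreDistributionSpec,
    SyntheticTruth,
    gen_two_class_scores,
    load_published_thresholds,
)

# one fixed seed for the oracle-equivalence suites, chosen once
ORACLE_SEED = 12345


@pytest.fixture(scope="session")
def gaussian_truth():
    """Equal-variance Gaussian two-class truth: f_P = N(2,1), f_B = N(0,1)."""
    return SyntheticTruth(
        pathogenic_spec=ScoreDistributionSpec.gaussian(2.0, 1.0),
        benign_spec=ScoreDistributionSpec.gaussian(0.0, 1.0),
        prior=0.046,
        seed=ORACLE_SEED,
    )


@pytest.fixture(scope="session")
def gaussian_scores_large(gaussian_truth):
    return gen_two_class_scores(gaussian_truth, 5000, 5000, tool="gauss", variant_type="deletion")


@pytest.fixture(scope="session")
def deletion_scale():
    return PointScale.from_prior(0.046)


@pytest.fixture(scope="session")
def published():
    return load_published_thresholds()
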