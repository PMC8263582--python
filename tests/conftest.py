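import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sigaudit as sa

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def pairwise_auc(scores, labels) -> float:
    """Independent brute-force AUC: count wins over all (pos, neg) pairs,
    ties as 1/2.  Pure-Python oracle, no ranking shortcut."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture
def worked_cohort() -> sa.ExpressionCohort:
    """4-sample, 2-gene cohort small enough to fit by hand.

    g1 = [1, 3, 5, 7], g2 = [2, 0, 2, 4]; first two samples respond.
    """
    return sa.ExpressionCohort(
        name="worked",
        genes=["g1", "g2"],
        samples=["s1", "s2", "s3", "s4"],
        values=np.array([[1.0, 3.0, 5.0, 7.0], [2.0, 0.0, 2.0, 4.0]]),
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture
def null_config() -> sa.SimulationConfig:
    """Default null study condition: 4 x 26 samples, 2000 genes, no signal."""
    return sa.SimulationConfig(seed=11)
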