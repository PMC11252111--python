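import numpy as np
import pytest

from lingsum import DiscreteFuzzySet, PipelineConfig
from lingsum.cohort import CohortSpec, generate_cohort

UNIVERSE = ("e1", "e2", "e3", "e4")


@pytest.fixture
def set_a():
    """Fuzzy set A = {0.8/e1, 0.9/e2, 1/e3, 0.2/e4} ("behind by age")."""
    return DiscreteFuzzySet.from_degrees(UNIVERSE, (0.8, 0.9, 1.0, 0.2))


@pytest.fixture
def set_b():
    """Fuzzy set B = {1/e1, 0.8/e2, 0.3/e3, 0.1/e4} ("high animation net dwell")."""
    return DiscreteFuzzySet.from_degrees(UNIVERSE, (1.0, 0.8, 0.3, 0.1))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(), seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Reduced feature set keeping pipeline runs fast in tests."""
    return PipelineConfig(
        et_features=("si_net_dwell_ms", "anim_net_dwell_ms",
                     "si_fixation_count", "anim_fixation_count"),
        composite_features=("cognitive_composite", "language_composite"),
        age_relative_features=("cognitive_age_months",
                               "receptive_communication_months"),
        seed=3,
    )


def random_fuzzy_set(rng: np.random.Generator, n: int) -> DiscreteFuzzySet:
    uni = tuple(f"e{i}" for i in range(n))
    return DiscreteFuzzySet.from_degrees(uni, np.round(rng.random(n), 3))
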