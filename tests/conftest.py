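import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from progressionkit.synthetic import (SimulationConfig, simulate_genetic_cohort,
                                      simulate_methylation_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genetic_cohort():
    """Shared small genetic cohort (10 patients, ~25 variants each)."""
    cfg = SimulationConfig(seed=11, n_patients=10, n_variants_min=20,
                           n_variants_max=30)
    return cfg, simulate_genetic_cohort(cfg)


@pytest.fixture(scope="session")
def small_methylation_cohort():
    """Shared paired methylation cohort (27 patients, 4000 CpGs)."""
    cfg = SimulationConfig(seed=13, n_patients=27, n_cpgs=4000,
                           frac_progression_cpgs=0.02)
    return cfg, simulate_methylation_cohort(cfg)
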