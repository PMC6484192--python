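import numpy as np
import pytest

from spikepharm import (
    BinnedRate,
    baseline_statistics,
    generate_cohort,
)


@pytest.fixture(scope="session")
def don15_cohort():
    """One seeded 16-unit cohort with the strong-dose response structure
    (10 excitatory, 2 inhibitory, 4 null ground-truth units)."""
    return generate_cohort(["don15"], seed=20260929)


@pytest.fixture
def reference_baseline():
    """Baseline statistics of 15 bins at rates [3,4,5]×5: mean 4 spikes/s,
    sample SD sqrt(10/14) ~ 0.845 (band at 2 SD: [2.310, 5.690])."""
    psth = BinnedRate(60.0, 0.0, np.array([3, 4, 5] * 5) * 60)
    return baseline_statistics(psth, 900.0)
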