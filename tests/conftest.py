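import numpy as np
import pytest

from larvadose.synthetic import (
    CohortGeneratorSpec,
    S11GeneratorSpec,
    simulate_cohort,
    simulate_s11,
)


@pytest.fixture(scope="session")
def rayleigh_sweep():
    """Well-stirred 8x8 sweep across the measured band."""
    freqs = np.linspace(1.0e9, 5.9e9, 197)
    return simulate_s11(S11GeneratorSpec(frequencies=freqs, n1=8, n2=8, seed=42))


@pytest.fixture(scope="session")
def rician_sweep():
    """Badly stirred sweep: fixed per-position offset 10x the stirred sd."""
    freqs = np.linspace(1.0e9, 5.9e9, 197)
    return simulate_s11(
        S11GeneratorSpec(
            frequencies=freqs, n1=8, n2=8, family="rician",
            stirred_scale=0.03, rician_offset=0.3, seed=42,
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study design (4 conditions x 5 runs x 168 larvae)."""
    return simulate_cohort(CohortGeneratorSpec(seed=0))


@pytest.fixture()
def small_cohort():
    """Reduced cohort for fast unit tests."""
    return simulate_cohort(
        CohortGeneratorSpec(seed=1, runs_per_condition=2, larvae_per_run=60)
    )
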