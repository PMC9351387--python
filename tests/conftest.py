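import numpy as np
import pytest

from countraj import CorrelationSpec, CountSeries, PowerSpec, SimSpec, simulate_series


@pytest.fixture
def small_series() -> CountSeries:
    """Tiny deterministic series with a gap (no time 4)."""
    return CountSeries(times=[1.0, 2.0, 3.0, 5.0, 6.0], counts=[2, 0, 3, 1, 4])


@pytest.fixture
def rate_series() -> CountSeries:
    return CountSeries(
        times=[1.0, 2.0, 3.0, 4.0], counts=[3, 5, 2, 4], totals=[2.0, 2.5, 2.0, 3.0]
    )


@pytest.fixture
def ar1_series() -> CountSeries:
    """Simulated AR1-correlated overdispersed series, N=40."""
    series, _ = simulate_series(
        SimSpec(
            n=40,
            mean_powers=(0.5,),
            beta=(0.5, 0.1),
            beta_prime=(0.3,),
            structure=CorrelationSpec("ar1"),
            rho=0.5,
            seed=7,
        )
    )
    return series


@pytest.fixture
def basic_spec() -> PowerSpec:
    return PowerSpec(mean_powers=(0.5,))
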