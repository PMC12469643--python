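import numpy as np
import pytest

from relaxsel.spin import InteractionConstants


@pytest.fixture(scope="session")
def constants() -> InteractionConstants:
    """Default spin-pair constants: 600.13 MHz, rNH 1.023 Å, Δσ −166 ppm."""
    return InteractionConstants()


@pytest.fixture(scope="session")
def dipolar_only() -> InteractionConstants:
    """CSA switched off; isolates the dipolar pathway."""
    return InteractionConstants(delta_sigma_ppm=0.0)


def quadrature_J(time_corr, omega: float, t_max: float, n: int = 200_000):
    """Independent spectral-density oracle: J(ω) = ∫₀^∞ C(t) cos(ωt) dt by
    dense trapezoid quadrature of the time-domain correlation function."""
    t = np.linspace(0.0, t_max, n)
    return float(np.trapezoid(time_corr(t) * np.cos(omega * t), t))
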