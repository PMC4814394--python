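import numpy as np
import pytest

from aakinetics import KineticParams, ObservationSeries
from aakinetics.presets import TRIAL_TIME_GRID


@pytest.fixture
def study_grid() -> np.ndarray:
    """The trial sampling grid: baseline plus seven postprandial samples."""
    return np.array(TRIAL_TIME_GRID)


@pytest.fixture
def whey_like_params() -> KineticParams:
    """Fast-absorption parameters of the magnitude seen for hydrolysates."""
    return KineticParams(k1=0.06, k3=0.03, x0=3.0, y0=2.0)


@pytest.fixture
def noise_free_series(study_grid, whey_like_params) -> ObservationSeries:
    from aakinetics import plasma_concentration

    return ObservationSeries(
        subject=1,
        supplement="High DH",
        analyte="TAA",
        times=study_grid,
        concentrations=plasma_concentration(whey_like_params, study_grid),
    )


def rk4_two_compartment(k1, k3, x0, y0, t_end, n_steps=4000):
    """Reference ODE integration of the two-compartment system.

    Integrates dY/dt = k1·[stomach not empty] − k3·Y with classic RK4,
    splitting exactly at the stomach-emptying time so the discontinuous
    right-hand side never spans a step. Independent of the closed form.
    """
    te = x0 / k1

    def integrate(y, a, b, rate):
        if b <= a:
            return y
        h = (b - a) / n_steps
        for i in range(n_steps):
            k_a = rate - k3 * y
            k_b = rate - k3 * (y + 0.5 * h * k_a)
            k_c = rate - k3 * (y + 0.5 * h * k_b)
            k_d = rate - k3 * (y + h * k_c)
            y = y + h / 6.0 * (k_a + 2 * k_b + 2 * k_c + k_d)
        return y

    y = integrate(y0, 0.0, min(t_end, te), k1)
    return integrate(y, min(t_end, te), t_end, 0.0)


def rk4_first_order(ka, k3, x0, y0, t_end, n_steps=4000):
    """Reference RK4 for the first-order-absorption (Bateman) system."""
    h = t_end / n_steps
    x, y = x0, y0
    for i in range(n_steps):
        def rhs(x, y):
            return -ka * x, ka * x - k3 * y

        dx1, dy1 = rhs(x, y)
        dx2, dy2 = rhs(x + 0.5 * h * dx1, y + 0.5 * h * dy1)
        dx3, dy3 = rhs(x + 0.5 * h * dx2, y + 0.5 * h * dy2)
        dx4, dy4 = rhs(x + h * dx3, y + h * dy3)
        x += h / 6.0 * (dx1 + 2 * dx2 + 2 * dx3 + dx4)
        y += h / 6.0 * (dy1 + 2 * dy2 + 2 * dy3 + dy4)
    return y
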