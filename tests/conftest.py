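import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gelmech as g

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

NONALIGNED = ["nonaligned_0.03", "nonaligned_0.1", "nonaligned_0.25"]
ALIGNED = ["aligned_0.03", "aligned_0.1", "aligned_0.25"]


@pytest.fixture(scope="session")
def scenario_params():
    """Published GOH parameter sets keyed by scenario name."""
    return {name: g.load_scenario(name)[0] for name in NONALIGNED + ALIGNED}


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def fd_biaxial_stress(params, lam_x, lam_y, h=1e-6):
    """Independent finite-difference oracle for the biaxial Cauchy stresses.

    For an incompressible membrane with the pressure eliminated by plane
    stress, sigma_ii = lambda_i * d/d lambda_i of the reduced strain energy
    U(lambda_x, lambda_y) with lambda_z = 1/(lambda_x lambda_y). Central
    differences with relative step h.
    """

    def U(lx, ly):
        return g.strain_energy(params, g.PlanarDeformation(lx, ly))

    hx, hy = h * lam_x, h * lam_y
    dUdx = (U(lam_x + hx, lam_y) - U(lam_x - hx, lam_y)) / (2.0 * hx)
    dUdy = (U(lam_x, lam_y + hy) - U(lam_x, lam_y - hy)) / (2.0 * hy)
    return lam_x * dUdx, lam_y * dUdy


def random_admissible_draw(rng):
    """One random (params, lambda_x, lambda_y) draw with a safe fiber exponent.

    Rejection-samples until the fiber exponent k2*<E>^2 stays well below the
    overflow guard, so every draw is an admissible state for all operations.
    """
    while True:
        params = g.MaterialParams(
            C10=float(10.0 ** rng.uniform(0.0, 1.7)),
            k1=float(10.0 ** rng.uniform(2.0, 4.7)),
            k2=float(10.0 ** rng.uniform(1.0, 3.05)),
            gamma_deg=float(rng.uniform(0.0, 90.0)),
            kappa=float(rng.uniform(0.0, 1.0 / 3.0)),
        )
        lam_x = float(rng.uniform(0.95, 1.08))
        lam_y = float(rng.uniform(0.95, 1.08))
        state = g.fiber_state(params, g.PlanarDeformation(lam_x, lam_y))
        if params.k2 * float(np.max(np.maximum(state.E_bar, 0.0))) ** 2 < 30.0:
            return params, lam_x, lam_y
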