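import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phosphocycle.cmc_model import CMCParams, PromoterHill

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def simple_params() -> CMCParams:
    """Symmetric toy cycle with a hand-solvable transfer curve."""
    return CMCParams(
        theta_k=1.0, theta_p=1.0, K_Mk=1.0, K_Mp=1.0,
        X_t=10.0, K_t=1.0, alpha=10.0, gamma=1.0,
        phi=PromoterHill(K_D=5.0),
    )


@pytest.fixture
def quasi_integral_params() -> CMCParams:
    """Saturated enzymes (K_Mp = 1e-3 X_t, X_t = 1e3 K_Mk), unsaturated promoter."""
    return CMCParams(
        theta_k=1.0, theta_p=1.0, K_Mk=1.0, K_Mp=1.0,
        X_t=1000.0, K_t=100.0, alpha=1e4, gamma=1.0,
        phi=PromoterHill(K_D=500.0),
    )


def random_params(rng: np.random.Generator, w_max: float = 0.9) -> CMCParams:
    """Log-uniform draw over well-conditioned cycle/expression parameters."""
    return CMCParams(
        theta_k=10 ** rng.uniform(-1, 1),
        theta_p=10 ** rng.uniform(-1, 1),
        K_Mk=10 ** rng.uniform(-2, 2),
        K_Mp=10 ** rng.uniform(-2, 2),
        X_t=10 ** rng.uniform(0, 3),
        K_t=10 ** rng.uniform(-1, 2),
        alpha=10 ** rng.uniform(1, 4),
        gamma=10 ** rng.uniform(-1, 1),
        rho=10 ** rng.uniform(-0.5, 0.5),
        w=rng.uniform(0.0, w_max),
        phi=PromoterHill(K_D=10 ** rng.uniform(0, 3), basal=rng.uniform(0, 0.2)),
    )
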