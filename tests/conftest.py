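import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csfclear import pk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def example_params() -> pk.PKParameters:
    """The reference two-compartment parameter set used across PK tests."""
    return pk.PKParameters(ka=0.2, tlag=0.8, cl=4.0, vc=10.0, q=2.0, vp=15.0,
                           dose=0.5)


def ode_concentration(params: pk.PKParameters, tgrid):
    """Independent stiff-ODE oracle for the depot two-compartment model."""
    from scipy.integrate import solve_ivp

    k10 = params.cl / params.vc
    k12 = params.q / params.vc
    k21 = params.q / params.vp

    def rhs(t, s):
        depot, central, peripheral = s
        flux = params.ka * depot if t > params.tlag else 0.0
        return [-flux,
                flux - (k10 + k12) * central + k21 * peripheral,
                k12 * central - k21 * peripheral]

    tgrid = np.asarray(tgrid, float)
    sol = solve_ivp(rhs, (0.0, float(tgrid[-1])), [params.dose, 0.0, 0.0],
                    t_eval=tgrid, method="LSODA", rtol=1e-11, atol=1e-13,
                    max_step=0.25)
    return sol.y[1] / params.vc


@pytest.fixture(scope="session")
def ode_oracle():
    return ode_concentration
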