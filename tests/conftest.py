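import numpy as np
import pytest

from ffrbench import (
    CFRLine,
    FluidProperties,
    NoiseModel,
    SyntheticVessel,
    VesselGeometry,
    build_cfr_line,
    generate_cohort,
    stenosis_coefficients,
)


@pytest.fixture(scope="session")
def default_line() -> CFRLine:
    """Population CFR line: slope 2.5 mL/min/mmHg through (20 mmHg, 0)."""
    return build_cfr_line(q_rest=50.0, cfr_normal=3.5, p_normal=90.0, p_zf=20.0)


@pytest.fixture()
def moderate_vessel(default_line) -> SyntheticVessel:
    """A mid-severity vessel with exactly known coefficients and FFR."""
    from ffrbench import PQCurveFit, solve_hyperemia

    geometry = VesselGeometry(3.0, 50.0, 10.0)
    coeffs = stenosis_coefficients(geometry, FluidProperties())
    fit = PQCurveFit(a=coeffs.a, b=coeffs.b, covariance=np.zeros((2, 2)), rmse=0.0, n_points=0)
    sol = solve_hyperemia(fit, p_a=90.0, line=default_line)
    return SyntheticVessel(
        id="toy",
        geometry=geometry,
        coefficients=coeffs,
        aortic_pressure=90.0,
        true_cfr_line=default_line,
        true_ffr=sol.ffr3d,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(28, seed=42)


@pytest.fixture()
def quiet_noise() -> NoiseModel:
    return NoiseModel(flow_relative_sd=0.0, pressure_relative_sd=0.0, seed=0)


def bisect_hyperemia(a: float, b: float, p_a: float, m: float, p_zf: float) -> float:
    """Independent oracle: bisection on g(Q) = m·(p_a − ΔP(Q) − p_zf) − Q.

    g is strictly decreasing for Q >= 0 with g(0) > 0 when p_a > p_zf, so
    plain bisection on a bracketing interval converges to the unique root.
    """
    def g(q):
        return m * (p_a - a * q - b * q * q - p_zf) - q

    lo, hi = 0.0, 10.0 * m * (p_a - p_zf) + 1.0
    assert g(lo) > 0 and g(hi) < 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
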