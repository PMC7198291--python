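import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ridkin as rk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> rk.KineticParameters:
    return rk.default_parameters()


@pytest.fixture(scope="session")
def default_masses(default_params) -> rk.SteadyStateMasses:
    return rk.steady_state(default_params)


@pytest.fixture(scope="session")
def toy_params() -> rk.KineticParameters:
    """Small, fast-turnover parameter set for cheap exact checks."""
    return rk.KineticParameters(
        absorption_efficiency=0.9,
        delay_time=0.2,
        l_5_4=10.0,
        l_6_5=4.0,
        l_7_5=1.5,
        l_8_5=0.8,
        l_5_6=0.05,
        l_5_7=0.4,
        l_0_6=0.01,
        dietary_intake=1.5,
        dose=1.0,
    )


@pytest.fixture(scope="session")
def default_grid() -> np.ndarray:
    return np.arange(0.0, 42.0 + 0.025, 0.05)


@pytest.fixture(scope="session")
def default_trajectory(default_params, default_grid) -> rk.TracerTrajectory:
    return rk.simulate_tracer(default_params, default_grid)


@pytest.fixture(scope="session")
def default_curve(default_params, default_masses, default_trajectory):
    return rk.coefficients_from_model(
        default_trajectory, default_masses, default_params
    )


@pytest.fixture(scope="session")
def superstudy_replicates(default_params):
    """Ten seeded replicates of the scaled-down super-person study.

    n = 20 theoretical subjects per replicate, lognormal parameter CVs
    0.3 on the store-exchange/catabolic rates and intake and 0.1 on the
    remaining rates, 5% multiplicative SA noise, default schedule with
    common day 4.  Shared session-wide because the replicates are the
    costliest computation in the suite.
    """
    from ridkin.population import StudyDesign, generate_subjects, run_superstudy

    reports = []
    for seed in range(1, 11):
        subjects = generate_subjects(default_params, None, n=20, seed=seed)
        report = run_superstudy(
            subjects, StudyDesign(seed=seed), init=default_params
        )
        reports.append(report)
    return reports
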