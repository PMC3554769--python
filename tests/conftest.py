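import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emtmir.calibration import CalibrationPrimitives, derive_parameter_set
from emtmir.io import default_parameters

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def primitives() -> CalibrationPrimitives:
    return CalibrationPrimitives()


@pytest.fixture(scope="session")
def params(primitives):
    """Parameter set derived fresh from the bundled primitives."""
    return derive_parameter_set(primitives)


@pytest.fixture(scope="session")
def bundled_params():
    """The parameter file shipped with the package."""
    return default_parameters()


@pytest.fixture(scope="session")
def egfr_mutant_traj(params):
    """Long-horizon trajectory of the EGFR-mutant cell (10x complex level)."""
    from emtmir.ode import ScenarioSpec, run_scenario
    grid = np.unique(np.concatenate([[0.0], np.geomspace(1e-2, 2.0e4, 1200)]))
    spec = ScenarioSpec(target_parameter="egfr_complex", value=10.0,
                        t_eval=2.0e4, t_grid=grid)
    return run_scenario(spec, params)
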