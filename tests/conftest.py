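import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dietrsm as dr

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def factors():
    return dr.study_factors()


@pytest.fixture(scope="session")
def design20():
    """The canonical 20-run rotatable design (8 factorial, 6 axial, 6 center)."""
    return dr.study_design()


@pytest.fixture(scope="session")
def models():
    return {r: dr.reference_model(r) for r in ("Bf", "F")}


@pytest.fixture(scope="session")
def noiseless_tables(design20, models):
    return {
        r: dr.simulate_measurements(design20, models[r], noise_sd=0.0,
                                    replicates_per_run=5, seed=0)
        for r in ("Bf", "F")
    }


@pytest.fixture(scope="session")
def toy_k2_fit():
    """A small noisy two-factor quadratic fit for diagnostic oracles."""
    rng = np.random.default_rng(12345)
    facs = [dr.Factor("a", 0.0, 1.0), dr.Factor("b", 0.0, 1.0)]
    des = dr.build_ccd(facs, n_center=5, alpha="rotatable")
    x = des.coded_matrix()
    y = 3.0 + 1.5 * x[:, 0] - 0.8 * x[:, 1] + 0.4 * x[:, 0] * x[:, 1] \
        + 0.6 * x[:, 0] ** 2 - 0.2 * x[:, 1] ** 2 + rng.normal(0, 0.5, len(x))
    return dr.fit_quadratic(x, y, representation="coded", factors=facs)
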