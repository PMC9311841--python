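import numpy as np
import pytest

from doripk import DoseRegimen, PopulationModel, TwoCompartmentParams


@pytest.fixture(scope="session")
def typical_params() -> TwoCompartmentParams:
    """Population typical values of the final doripenem model."""
    m = PopulationModel()
    return TwoCompartmentParams(m.tv_cl, m.tv_vc, m.tv_q, m.tv_vp)


@pytest.fixture(scope="session")
def pop_model() -> PopulationModel:
    return PopulationModel()


@pytest.fixture(scope="session")
def random_param_sets():
    """1000 random valid parameter sets spanning realistic magnitudes."""
    rng = np.random.default_rng(20220958)
    n = 1000
    return [
        TwoCompartmentParams(
            CL=float(10 ** rng.uniform(0, 1.7)),
            Vc=float(10 ** rng.uniform(0.3, 1.7)),
            Q=float(10 ** rng.uniform(0, 1.3)),
            Vp=float(10 ** rng.uniform(0.3, 1.5)),
        )
        for _ in range(n)
    ]


def q8h(dose_g, t_inf, steady=True):
    return DoseRegimen.from_grams(dose_g, t_inf, tau=8.0, n_doses=None if steady else 1)
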