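import numpy as np
import pytest

from oscillometry import ERICParameters, FitOptions, eval_eric, load_fixture

IOS_GRID = (3.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@pytest.fixture
def table7_oc():
    return load_fixture("table7_oc").payload


@pytest.fixture
def table7_noc():
    return load_fixture("table7_noc").payload


@pytest.fixture
def sai_params():
    """SAI-like eRIC truth (published group means; Rc/I calibration values)."""
    return ERICParameters(Rc=0.40, I=0.0018, Rp=0.824, Cp=0.045)


@pytest.fixture
def sai_spectrum(sai_params):
    return eval_eric(sai_params, IOS_GRID)


def random_physiological_params(rng: np.random.Generator) -> ERICParameters:
    """Draw circuit constants from the paediatric physiological range."""
    return ERICParameters(
        Rc=rng.uniform(0.1, 1.0),
        I=rng.uniform(5e-4, 5e-3),
        Rp=rng.uniform(0.1, 1.5),
        Cp=rng.uniform(0.01, 0.3),
    )
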