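import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from spheroidfit import (GeneratorConfig, MeasurementTable, NoiseModel,
                         ReducedParameters, generate_dataset, make_design,
                         truth_record)


@pytest.fixture(scope="session")
def theta_star() -> ReducedParameters:
    """Reference truth for synthetic studies: reaches phase 3 by mid-run."""
    return ReducedParameters(Ro0=120.0, Rc=150.0, s=0.3, gamma=1.0, Q=0.7)


@pytest.fixture(scope="session")
def noise_star() -> NoiseModel:
    """Plug-in observation variances of order 10 um standard deviation."""
    return NoiseModel(sigma2_outer=81.0, sigma2_inhibited=144.0,
                      sigma2_necrotic=144.0)


@pytest.fixture(scope="session")
def design3_resA():
    return make_design("design3_resA")


@pytest.fixture(scope="session")
def noisy_table(theta_star, noise_star, design3_resA) -> MeasurementTable:
    cfg = GeneratorConfig(theta=theta_star, noise=noise_star,
                          design=design3_resA, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_table(theta_star, noise_star, design3_resA) -> MeasurementTable:
    cfg = GeneratorConfig(theta=theta_star, noise=noise_star,
                          design=design3_resA, seed=7)
    return truth_record(cfg)[1]
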