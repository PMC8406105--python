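import numpy as np
import pytest

from openapco.preprocessing import build_samples
from openapco.synthetic import SimConfig, emulate_apco, emulate_hr, emulate_pac, generate_case
from openapco.types import Device


@pytest.fixture
def float64_autodiff():
    """High-precision mode for numerical gradient checks."""
    from openapco import autodiff

    prev = autodiff.default_dtype()
    autodiff.set_default_dtype(np.float64)
    yield
    autodiff.set_default_dtype(prev)


@pytest.fixture(scope="session")
def clean_case():
    """One 10-min synthetic case with constant trajectories."""
    return generate_case(SimConfig(duration_s=600.0, seed=11), case_id="clean")


@pytest.fixture(scope="session")
def apco_samples():
    """Preprocessed samples of a clean APCO-role case."""
    from dataclasses import replace

    rec, gt = generate_case(SimConfig(duration_s=600.0, seed=12), case_id="apco0")
    rec = replace(rec, trends=[emulate_apco(gt, fluct_sd=8.0, seed=13)])
    samples, report = build_samples(rec, Device.APCO)
    return samples, report, gt


@pytest.fixture(scope="session")
def pac_samples():
    """Preprocessed samples of a clean PAC-role case."""
    from dataclasses import replace

    rec, gt = generate_case(SimConfig(duration_s=600.0, seed=14), case_id="pac0")
    rec = replace(rec, trends=[emulate_pac(gt), emulate_hr(gt)])
    samples, report = build_samples(rec, Device.PAC)
    return samples, report, gt
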