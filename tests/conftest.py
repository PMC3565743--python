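import numpy as np
import pytest

from rsfcd import assemble_model
from rsfcd.assay import AssayConfig, noiseless_trace


@pytest.fixture(scope="session")
def model_I():
    return assemble_model("I")


@pytest.fixture(scope="session")
def model_I_log():
    return assemble_model("I", activity_form="log")


@pytest.fixture(scope="session")
def model_II_log():
    return assemble_model("II", activity_form="log")


@pytest.fixture(scope="session")
def model_III_log():
    return assemble_model("III", activity_form="log")


@pytest.fixture(scope="session")
def log_models(model_I_log, model_II_log, model_III_log):
    return {"I": model_I_log, "II": model_II_log, "III": model_III_log}


@pytest.fixture(scope="session")
def steady_I_at_0(model_I):
    return model_I.steady_state(0.0)


@pytest.fixture(scope="session")
def noiseless_assay_trace(model_I):
    """Noiseless tethered-cell-like trace from the default model I truth."""
    return noiseless_trace(AssayConfig(truth=model_I, noise_sd=0.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
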