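import numpy as np
import pytest

from ppgru.activation_approx import build_sigmoid_cheb
from ppgru.he_core import HEParams, keygen
from ppgru.plain_model import ClampedReference
from ppgru.secure_gru import SecureSession
from ppgru.synthetic_data import CohortConfig, gen_cohort, gen_weights


@pytest.fixture(scope="session")
def he_params():
    return HEParams()


@pytest.fixture(scope="session")
def keys(he_params):
    return keygen(he_params, 1)


@pytest.fixture(scope="session")
def sig_poly():
    return build_sigmoid_cheb(24, (-10.0, 10.0))


@pytest.fixture(scope="session")
def clamped_ref(sig_poly):
    return ClampedReference(sig_poly, R=9, R_tanh=4)


@pytest.fixture()
def session(keys, sig_poly):
    return SecureSession(keys=keys, sig_poly=sig_poly, protocol_rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_model():
    """Calibrated random weights with ~5% of pre-activations out of range."""
    return gen_weights(outlier_frac=0.05, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return gen_cohort(CohortConfig(n_patients=12, seed=21))
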