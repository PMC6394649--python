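"""Shared fixtures: a linear mixed model (exact oracles exist) and toy designs."""

import numpy as np
import pytest

from cwresqa.models import Design, ErrorModel, NLMEModel


def make_linear_model(theta=1.0, omega_var=0.1, sigma_var=0.05):
    """y_ij = theta + eta_i + eps_ij: the FOCE linearization is exact here,
    so closed-form compound-symmetry likelihood results apply."""

    def pred(th, eta, design):
        eta = np.asarray(eta, dtype=float)
        base = th[0] + eta[..., 0]
        return np.broadcast_to(
            base[..., None], eta.shape[:-1] + (design.n_obs,)
        ).copy()

    return NLMEModel(
        name="linear",
        pred=pred,
        theta=np.array([theta]),
        omega=np.array([[omega_var]]),
        errors=(ErrorModel(add_var=sigma_var),),
        dv_labels=("dv1",),
        theta_positive=(False,),
    )


def flat_design(n_obs):
    return Design(times=np.arange(n_obs, dtype=float), dvid=np.zeros(n_obs, dtype=int))


@pytest.fixture
def linear_model():
    return make_linear_model()


@pytest.fixture
def design5():
    return flat_design(5)
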