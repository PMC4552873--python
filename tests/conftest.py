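"""Shared fixtures: small calibrated networks and the 66-region reference.

Session scope keeps the expensive pieces (feedback-inhibition calibration,
stationary moment solutions) to one computation per run.
"""

import numpy as np
import pytest

from braindmf.data_io import Connectome
from braindmf.fic import calibrate_fic
from braindmf.lna import solve_moments
from braindmf.model import coupling_matrix
from braindmf.presets import default_params, reference_connectome, visual_protocol
from braindmf.synthetic import ModularGraphSpec, generate_modular_connectome


@pytest.fixture(scope="session")
def small_conn():
    """8-node modular graph at the empirical per-link weight."""
    spec = ModularGraphSpec(
        n_nodes=8, n_modules=2, q=0.4, p=0.5, scale=0.025, seed=11
    )
    return generate_modular_connectome(spec)


@pytest.fixture(scope="session")
def small_params(small_conn):
    params = default_params()
    res = calibrate_fic(small_conn, params, verify=False)
    return params.with_w_EI(res.w_EI)


@pytest.fixture(scope="session")
def small_spont(small_conn, small_params):
    return solve_moments(small_conn, small_params)


@pytest.fixture(scope="session")
def small_W(small_conn, small_params):
    return coupling_matrix(small_conn, small_params)


@pytest.fixture(scope="session")
def ref_conn():
    return reference_connectome()


@pytest.fixture(scope="session")
def ref_fic(ref_conn):
    return calibrate_fic(ref_conn, default_params())


@pytest.fixture(scope="session")
def ref_params(ref_fic):
    return default_params().with_w_EI(ref_fic.w_EI)


@pytest.fixture(scope="session")
def ref_spont(ref_conn, ref_params):
    return solve_moments(ref_conn, ref_params)


@pytest.fixture(scope="session")
def ref_task(ref_conn, ref_params, ref_spont):
    protocol = visual_protocol(ref_conn)
    return solve_moments(
        ref_conn,
        ref_params,
        I_ext=protocol.constant_current(ref_conn.n_regions),
        S0=ref_spont.mu,
    )


@pytest.fixture(scope="session")
def ref_W(ref_conn, ref_params):
    return coupling_matrix(ref_conn, ref_params)


@pytest.fixture
def tiny_conn():
    """Two disconnected regions: isolated-node behaviour."""
    return Connectome(weights=np.zeros((2, 2)))
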