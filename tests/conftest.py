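import numpy as np
import pytest

from carechain import AmiChainConfig, LiteratureEvidence, analyze_chain, build_current_state


@pytest.fixture(scope="session")
def evidence():
    return LiteratureEvidence()


@pytest.fixture(scope="session")
def config():
    return AmiChainConfig()


@pytest.fixture(scope="session")
def current_chain(evidence, config):
    return build_current_state(evidence, config)


@pytest.fixture(scope="session")
def current_result(current_chain):
    return analyze_chain(current_chain)


def fixed_point_absorption(Q, R, tol=1e-14, max_iter=1_000_000):
    """Independent oracle: iterate the first-step equations B <- Q B + R."""
    Q = np.asarray(Q, dtype=float)
    R = np.asarray(R, dtype=float)
    B = np.zeros_like(R)
    for _ in range(max_iter):
        B_next = Q @ B + R
        if np.max(np.abs(B_next - B)) < tol:
            return B_next
        B = B_next
    raise RuntimeError("fixed-point iteration did not converge")


def fixed_point_fundamental(Q, tol=1e-14, max_iter=1_000_000):
    """Independent oracle: iterate N <- I + Q N (Neumann series)."""
    Q = np.asarray(Q, dtype=float)
    I = np.eye(Q.shape[0])
    N = np.zeros_like(Q)
    for _ in range(max_iter):
        N_next = I + Q @ N
        if np.max(np.abs(N_next - N)) < tol:
            return N_next
        N = N_next
    raise RuntimeError("fixed-point iteration did not converge")
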