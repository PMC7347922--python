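import numpy as np
import pytest

from mvtlearn import SessionDesign, SubjectParams, simulate_subject


@pytest.fixture(scope="session")
def design_exp1():
    return SessionDesign("exp1", "RichPoor")


@pytest.fixture(scope="session")
def short_design():
    """Two 300-s blocks: quick sessions for unit tests."""
    return SessionDesign("exp2", "PoorRich", duration_seconds=300)


@pytest.fixture(scope="session")
def asym_params():
    """Group-mean asymmetric parameters (first experiment)."""
    return SubjectParams(
        "asymmetric", alpha_pos=0.005, alpha_neg=0.0016, beta0=-1.8179, beta1=0.0748
    )


@pytest.fixture(scope="session")
def sym_params():
    return SubjectParams("symmetric", alpha=0.0218, beta0=0.9855, beta1=0.076)


@pytest.fixture(scope="session")
def sim_log(short_design, asym_params):
    log, trace = simulate_subject(short_design, asym_params, seed=11, trace=True)
    return log, trace
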