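import numpy as np
import pytest

from tmdimer import (
    ir_system,
    igf1r_system,
    get_preset,
    generate,
    compute_metrics,
)


@pytest.fixture(scope="session")
def ir():
    return ir_system()


@pytest.fixture(scope="session")
def igf():
    return igf1r_system()


@pytest.fixture(scope="session")
def xshape_run(ir):
    """One short bound-state replica of the IR X-shaped preset."""
    traj, truth = generate(ir, get_preset("ir_xshape"), n_frames=2000, seed=42)
    return traj, truth


@pytest.fixture(scope="session")
def xshape_metrics(ir, xshape_run):
    traj, _ = xshape_run
    return compute_metrics(traj, ir)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
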