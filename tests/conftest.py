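import numpy as np
import pytest

from permeus import ThermoState, default_window_schedule
from permeus import synthetic as syn
from permeus import wham as wh


@pytest.fixture(scope="session")
def thermo300():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def square_model():
    return syn.make_membrane_model("square_barrier")


@pytest.fixture(scope="session")
def popc_model():
    return syn.make_membrane_model("popc_like")


@pytest.fixture(scope="session")
def square_reus_dataset(square_model):
    """Moderate-length replica-exchange run on the square-barrier landscape,
    shared by the WHAM unit tests (unit-test scale, coarser than the
    recovery benchmarks)."""
    schedule = default_window_schedule()
    series, log = syn.run_reus(
        square_model,
        schedule,
        dt=0.05,
        n_steps=200_000,
        exchange_interval_steps=200,
        seed=101,
        sample_every=10,
        n_equil_steps=10_000,
    )
    return schedule, series, log


@pytest.fixture(scope="session")
def square_wham(square_model, square_reus_dataset):
    schedule, series, _ = square_reus_dataset
    return wh.solve_wham_1d(schedule, series, thermo=square_model.thermo)


def boltzmann_rejection_sample(model, n, seed, zmax=None):
    """Direct rejection sampling from exp(-beta G) on the model's z range.

    Independent of the Langevin integrator: serves as the sampling oracle
    for single-window (unbiased) WHAM checks.
    """
    rng = np.random.default_rng(seed)
    lo, hi = model.z_range
    if zmax is not None:
        hi = zmax
    out = []
    gmin = model.G(np.linspace(lo, hi, 2001)).min()
    beta = model.thermo.beta
    while sum(len(o) for o in out) < n:
        z = rng.uniform(lo, hi, 4 * n)
        acc = rng.random(4 * n) < np.exp(-beta * (model.G(z) - gmin))
        out.append(z[acc])
    return np.concatenate(out)[:n]
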