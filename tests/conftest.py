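import numpy as np
import pytest
from hypothesis import settings

from phenocart import growth, plate_io, simulate as sim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_run():
    """Two sample wells + two background wells, 5 timepoints."""
    times = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
    wells = {
        "A1": np.array([0.08, 0.08, 0.08, 0.08, 0.08]),
        "A2": np.array([0.07, 0.09, 0.07, 0.09, 0.08]),
        "B1": np.array([0.18, 0.28, 0.48, 0.68, 0.70]),
        "B2": np.array([0.08, 0.08, 0.08, 0.08, 0.08]),
    }
    return plate_io.PlateRun(run_id="toy", times=times, wells=wells)


@pytest.fixture
def toy_layout():
    return plate_io.PlateLayout(
        roles={"A1": "background", "A2": "background", "B1": "sample", "B2": "sample"},
        combinations={"B1": "c1", "B2": "c1"},
    )


@pytest.fixture
def small_scenario():
    """A reduced design (C=40, N=3) that still carries the planted structure."""
    return sim.Scenario(n_combinations=40, n_replicates=3, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """One full default-scenario dataset with extracted growth table.

    Session-scoped: several tests inspect different aspects of the same
    simulated study.
    """
    sc = sim.Scenario(seed=11)
    data = sim.simulate_dataset(sc)
    curves = []
    for run, lay in zip(data.runs, data.layouts):
        curves.extend(growth.subtract_background(run, lay))
    records = growth.extract_all(curves)
    refined, removal_log = growth.refine_dataset(records)
    return {
        "scenario": sc,
        "data": data,
        "curves": curves,
        "records": records,
        "refined": refined,
        "removal_log": removal_log,
    }


def logistic_curve(r, K, od0=1e-3, lag=1.5, duration=48.0, dt=0.5, noise=0.0, seed=0):
    """Noise-free (or noisy) logistic GrowthCurve helper for tests."""
    t = np.arange(int(round(duration / dt)) + 1) * dt
    od = sim.logistic_od(t, r, K, od0, lag)
    if noise:
        od = od + np.random.default_rng(seed).normal(0, noise, len(t))
    return growth.GrowthCurve("test", t, od)
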