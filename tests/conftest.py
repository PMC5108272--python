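import numpy as np
import pytest

from litterflame.burn_core import BurnTrial, ThermocoupleTrace
from litterflame.synth import SimulationConfig, gen_experiment


def make_trace(sensor_id, position, points):
    """Piecewise-linear trace from (time, temp) vertices sampled as given."""
    t, temp = zip(*points)
    return ThermocoupleTrace(sensor_id=sensor_id, position=position,
                             times=np.array(t, float), temperatures=np.array(temp, float))


def flat_trace(sensor_id, position, baseline=18.0, duration=120, dt=1.0):
    t = np.arange(0.0, duration, dt)
    return ThermocoupleTrace(sensor_id=sensor_id, position=position,
                             times=t, temperatures=np.full_like(t, baseline))


def make_trial(traces, trial_id="T1", components=None, mcs=None, residue=50.0,
               source_ignition=10.0, reached_edge=None):
    return BurnTrial(
        trial_id=trial_id, block="B1",
        components=components or [("SpA", 100.0)],
        moisture_contents=mcs or [0.07],
        post_burn_oven_dry_mass=residue,
        ignition_time_of_source=source_ignition,
        traces=traces, reached_edge_observed=reached_edge,
    )


def six_flat_traces(baseline=18.0):
    traces = [flat_trace("C", "center", baseline)]
    traces += [flat_trace(f"O{i}", "outer", baseline) for i in range(1, 6)]
    return traces


@pytest.fixture(scope="session")
def small_experiment():
    """A small full-trace experiment: 8 species, 4 pairs, 2 blocks."""
    cfg = SimulationConfig(rng_seed=11, n_species=8, n_pairs=4, replicate_blocks=2,
                           n_moss_species=1, n_dense_species=1)
    return gen_experiment(cfg, with_traces=True)


@pytest.fixture(scope="session")
def default_metrics_experiment():
    """The default 340-trial design on the metrics-only fast path."""
    cfg = SimulationConfig(rng_seed=4)
    return gen_experiment(cfg, with_traces=False)
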