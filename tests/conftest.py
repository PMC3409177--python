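import numpy as np
import pytest

from synaptenacity import (
    GeneratorParams,
    NeuronRecord,
    PunctumTrace,
    simulate_trace_population,
)


@pytest.fixture
def small_params():
    """A fast, fully stochastic parameter bundle for generator tests."""
    return GeneratorParams(
        n_puncta=20,
        n_timepoints=25,
        dt=10.0,
        fluctuation_sd=0.04,
        reconfiguration_sd=0.02,
        loss_prob=0.1,
        measurement_noise_sd=10.0,
        seed=42,
    )


@pytest.fixture
def quiet_params():
    """All stochastic terms off: traces must be exactly deterministic."""
    return GeneratorParams(
        n_puncta=5,
        n_timepoints=12,
        fluctuation_sd=0.0,
        reconfiguration_sd=0.0,
        size_spread_sd=0.0,
        bleach_rate=0.0,
        loss_prob=0.0,
        measurement_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def wt_record(small_params):
    records, _ = simulate_trace_population(small_params, "wt")
    return records[0]


def make_record(matrix, t=None, neuron_id="n0", **kw) -> NeuronRecord:
    """Build a NeuronRecord from a (puncta, time) fluorescence matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if t is None:
        t = np.arange(matrix.shape[1], dtype=float) * 10.0
    rec = NeuronRecord(neuron_id=neuron_id, **kw)
    for i, row in enumerate(matrix):
        rec.traces.append(PunctumTrace(punctum_id=f"p{i}", t=t, F=row))
    return rec
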