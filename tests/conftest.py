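import numpy as np
import pytest

import corrlif as cl


@pytest.fixture(scope="session")
def neuron():
    return cl.NeuronParams()


@pytest.fixture(scope="session")
def syn():
    return cl.SynapseParams()


@pytest.fixture
def make_inputs():
    """Build a NeuronInputs from explicit excitatory/inhibitory spike times."""

    def _make(exc_times, inh_times, duration):
        exc = cl.SpikeTrainEnsemble(
            (cl.SpikeTrain(0, np.asarray(exc_times, dtype=float), duration),),
            cl.EXCITATORY)
        inh = cl.SpikeTrainEnsemble(
            (cl.SpikeTrain(1, np.asarray(inh_times, dtype=float), duration),),
            cl.INHIBITORY)
        return cl.NeuronInputs(exc, inh)

    return _make


@pytest.fixture(scope="session")
def sd_mother_rate():
    """SD mother rate tuned to ~1 Hz output in the unjittered condition."""
    return cl.tune_sd_mother_rate(base_seed=101)


@pytest.fixture(scope="session")
def sd_mother_rate_jitter30():
    """SD mother rate tuned to ~1 Hz output with 30-ms input jitter."""
    return cl.tune_sd_mother_rate(jitter_width=30.0, base_seed=101)
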