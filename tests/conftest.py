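import numpy as np
import pytest

from micturition import ModelParams
from micturition.synthetic import GeneratorConfig, generate_recording


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_recording():
    """One default synthetic session shared by read-only tests."""
    return generate_recording(GeneratorConfig(), n_voids=12, seed=7)


@pytest.fixture(scope="session")
def noiseless_recording():
    cfg = GeneratorConfig(pressure_noise_sd=0.0)
    return generate_recording(cfg, n_voids=10, seed=2, with_emg=False)


@pytest.fixture(scope="session")
def ppn_calibration():
    """Session-scoped synapse calibration (the search takes ~half a minute)."""
    from micturition.ppn import NeuronParams, calibrate_synapses

    neuron = NeuronParams()
    return neuron, calibrate_synapses(neuron)
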