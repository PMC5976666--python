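import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from slicephys import (
    NeuronRecording,
    PassiveModel,
    SpikeModel,
    StepDescriptor,
    Sweep,
)


@pytest.fixture
def quiet_passive() -> PassiveModel:
    """Default passive model without measurement noise."""
    return PassiveModel(noise_sd_mv=0.0)


@pytest.fixture
def passive() -> PassiveModel:
    return PassiveModel()  # 0.2 mV noise


@pytest.fixture
def spike_model() -> SpikeModel:
    return SpikeModel()


@pytest.fixture
def step_m100() -> StepDescriptor:
    return StepDescriptor(amplitude_pa=-100.0, onset_s=0.2, duration_s=1.0)


def make_sweep(voltage, rate=50_000.0, amplitude=100.0, onset=0.2,
               duration=1.0, sweep_id="sw0") -> Sweep:
    return Sweep(
        voltage_mv=np.asarray(voltage, dtype=float),
        sampling_rate_hz=rate,
        step=StepDescriptor(amplitude, onset, duration),
        sweep_id=sweep_id,
    )


def flat_sweep(v_mv=-70.0, rate=50_000.0, n=70_000, amplitude=100.0,
               sweep_id="flat") -> Sweep:
    return make_sweep(np.full(n, v_mv), rate=rate, amplitude=amplitude,
                      sweep_id=sweep_id)


def recording_from_sweeps(sweeps, neuron_id="n0", **kwargs) -> NeuronRecording:
    return NeuronRecording(neuron_id=neuron_id, sweeps=list(sweeps), **kwargs)
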