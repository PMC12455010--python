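import numpy as np
import pytest

from kvinact import ConditionSpec, GatingModel, GlycoformMixture, NoiseModel, make_protocol

ZERO_NOISE = NoiseModel(baseline_sd=0.0, leak_conductance=0.0)


@pytest.fixture
def plus80_protocol():
    """Default sweep timing but only the +80 mV target step (fast to simulate)."""
    return make_protocol(step_potentials=[80.0])


@pytest.fixture
def tiny_protocol():
    """Short two-step protocol for I/O and structural tests."""
    return make_protocol(
        step_potentials=[0.0, 80.0], pre_step_duration=10.0, step_duration=50.0,
        sampling_rate=2.0,
    )


def single_component_mixture(k=1, mean_latency_ms=50.0, g_max=100.0, f_ss=0.0, **kwargs):
    model = GatingModel(g_max=g_max, k=k, lam=k / mean_latency_ms, f_ss=f_ss, **kwargs)
    return GlycoformMixture.single(model)


@pytest.fixture
def fixed_spec():
    """One-condition spec with a deterministic single-component sampler."""

    def sampler(rng):
        return single_component_mixture(k=4, mean_latency_ms=120.0)

    return ConditionSpec("fixed", sampler, n_cells=4)
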