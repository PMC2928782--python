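import numpy as np
import pytest

from cytolink import gating, synth


@pytest.fixture(scope="session")
def default_population():
    """Mid-size paired population with contamination, shared across tests."""
    truth = synth.PopulationTruth(n_cells=5000, n_micro=500, seed=42)
    micro, flow = synth.generate_paired_population(truth)
    return truth, micro, flow


@pytest.fixture(scope="session")
def gated_population(default_population):
    truth, micro, flow = default_population
    slope = gating.fit_scatter_axis(flow)
    gate = gating.choose_cuts(flow, slope)
    return truth, micro, gating.gate_events(flow, gate)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
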