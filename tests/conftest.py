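import numpy as np
import pytest

from navsim import DrugModel, GatingParams, NeuronParams
from navsim import neuron


GS5 = DrugModel(concentration_uM=5.0)


@pytest.fixture(scope="session")
def wt_params() -> GatingParams:
    return GatingParams()


@pytest.fixture(scope="session")
def mutant_params() -> GatingParams:
    """Channel with a 5% imposed persistent-current fraction."""
    return GatingParams(P_persist=0.05)


@pytest.fixture(scope="session")
def cell() -> NeuronParams:
    return NeuronParams()


@pytest.fixture(scope="session")
def gs967() -> DrugModel:
    return GS5


# --- shared (expensive) firing simulations -------------------------------


@pytest.fixture(scope="session")
def wt_firing_140(cell, wt_params):
    return neuron.simulate(cell, wt_params, inj_pA=140.0)


@pytest.fixture(scope="session")
def mutant_firing_140(cell, mutant_params):
    return neuron.simulate(cell, mutant_params, inj_pA=140.0)


@pytest.fixture(scope="session")
def wt_scan(cell, wt_params):
    """WT rheobase scan on a 10 pA grid spanning the expected bracket."""
    sched = neuron.InjectionSchedule(amplitudes_pA=np.arange(60.0, 201.0, 10.0))
    return neuron.rheobase_scan(cell, wt_params, schedule=sched)


@pytest.fixture(scope="session")
def mutant_scan(cell, mutant_params):
    sched = neuron.InjectionSchedule(amplitudes_pA=np.arange(60.0, 201.0, 10.0))
    return neuron.rheobase_scan(cell, mutant_params, schedule=sched)
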