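import numpy as np
import pytest
from hypothesis import settings

import cytoquant as cq

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_noiseless_scenario(median=2000.0, cv=1.0, n_cells=500, gain=1.0,
                            autofluor_pe=0.0, seed=11, **kwargs):
    """Scenario with every stochastic nuisance switched off: no
    instrument noise, no autofluorescence spread, no non-target
    populations, noiseless beads."""
    return cq.ScenarioConfig(
        name="noiseless",
        receptor_distribution=cq.ReceptorDistribution(median=median, cv=cv),
        n_cells=n_cells,
        n_replicates=kwargs.pop("n_replicates", 2),
        instrument=cq.Instrument(gain=gain, noise_cv=0.0,
                                 autofluor_pe=autofluor_pe, autofluor_cv=0.0),
        populations=cq.Populations(contaminant_fraction=0.0, debris_fraction=0.0,
                                   doublet_fraction=0.0),
        bead=cq.synthetic_cytometry.BeadConfig(n_per_level=50, noise_cv=0.0),
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def noiseless_scenario():
    return make_noiseless_scenario()


@pytest.fixture
def small_scenario():
    """Realistic but small: noise, autofluorescence and all event classes."""
    return cq.ScenarioConfig(
        name="small",
        receptor_distribution=cq.ReceptorDistribution(median=1800, cv=1.1),
        n_cells=3000,
        n_replicates=2,
        seed=5,
    )


@pytest.fixture
def event_table(rng):
    n = 200
    import pandas as pd

    data = pd.DataFrame({
        "fsc": rng.uniform(10, 1000, n),
        "ssc": rng.uniform(10, 1000, n),
        "fl1": rng.uniform(0.1, 100, n),
        "fl2": rng.uniform(0.1, 5000, n),
    })
    return cq.EventTable(data=data, metadata={"sample_id": "fixture"})
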