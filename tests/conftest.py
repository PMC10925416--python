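import numpy as np
import pytest

import dynconn as dc


@pytest.fixture
def single_circuit_spec():
    """Noise-free single planted circuit with one anti-correlated member."""
    return dc.SimSpec(
        n_neurons=6,
        n_animals=2,
        n_timepoints=300,
        circuits=(dc.PlantedCircuit(members=(0, 1, 2), window=(50, 200)),),
        noise_sd=0.0,
        baseline_drift_sd=0.0,
        seed=11,
    )


@pytest.fixture
def two_circuit_spec():
    """Two disjoint circuits in disjoint windows, low noise."""
    return dc.SimSpec(
        n_neurons=12,
        n_animals=5,
        n_timepoints=400,
        circuits=(
            dc.PlantedCircuit(members=(0, 1, 2, 3), window=(60, 180)),
            dc.PlantedCircuit(members=(5, 6, 7, 8), window=(230, 350)),
        ),
        noise_sd=0.05,
        baseline_drift_sd=0.0,
        seed=3,
    )


@pytest.fixture
def two_cliques_graph():
    """Two disjoint uniform-weight 4-cliques."""
    iu, ju = np.triu_indices(4, 1)
    src = np.concatenate([iu, iu + 4])
    dst = np.concatenate([ju, ju + 4])
    return dc.WeightedGraph(list(range(8)), src, dst, np.full(12, 0.9))


def random_weighted_graph(n, p, rng, w_lo=0.1, w_hi=1.0):
    iu, ju = np.triu_indices(n, 1)
    keep = rng.random(len(iu)) < p
    return dc.WeightedGraph(
        list(range(n)), iu[keep], ju[keep], rng.uniform(w_lo, w_hi, keep.sum())
    )
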