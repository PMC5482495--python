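import numpy as np
import pandas as pd
import pytest

import gitscore as gs


@pytest.fixture
def toy_fd():
    """Three genes, one compound: FD = (A: -1, B: -2, C: +1)."""
    df = pd.DataFrame({"c1": [-1.0, -2.0, 1.0]}, index=["A", "B", "C"])
    return gs.FitnessMatrix(df)


@pytest.fixture
def toy_net():
    """Edges A-B (-0.5) and A-C (+0.5); no B-C edge."""
    return gs.GINetwork.from_edges([("A", "B", -0.5), ("A", "C", 0.5)])


@pytest.fixture
def toy_nbh(toy_net):
    return gs.truncate(toy_net, None)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-target simulation shared across fast tests."""
    spec = gs.SimulationSpec(n_genes=120, n_compounds=8, seed=11)
    net = gs.simulate_network(spec)
    truth = gs.plant_targets(net, spec)
    return {
        "spec": spec,
        "net": net,
        "truth": truth,
        "bench": gs.make_benchmark(truth),
        "fd_hip": gs.simulate_hip(net, truth, spec),
        "fd_hop": gs.simulate_hop(net, truth, spec),
        "nbh": gs.truncate(net, 100),
    }


def dense_random_instance(rng, n_genes, n_compounds=5, edge_p=1.0):
    """Dense random signed network + complete FD matrix, with the dense
    adjacency returned for closed-form oracles."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    G = np.zeros((n_genes, n_genes))
    edges = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_p:
                w = rng.normal(0, 0.3)
                if w == 0.0:
                    continue
                G[i, j] = G[j, i] = w
                edges.append((genes[i], genes[j], w))
    net = gs.GINetwork.from_edges(edges)
    fd = pd.DataFrame(
        rng.normal(0, 1, size=(n_genes, n_compounds)),
        index=genes,
        columns=[f"c{j}" for j in range(n_compounds)],
    )
    return gs.FitnessMatrix(fd), net, G
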