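import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cooccurnet import CooccurrenceNetwork, OtuTable, SimConfig
from cooccurnet.simulate import simulate_bundle


@pytest.fixture(scope="session")
def strong_fit():
    """Strong-signal single-fraction study, fitted pooled over the grid.

    Returns (bundle, ground_truth, results); shared across tests because
    the fit is the expensive step.
    """
    config = SimConfig.strong_signal(seed=0)
    bundle, truth = simulate_bundle(config)
    results = CooccurrenceNetwork(bundle, pooled=True).fit(seed=0)
    return bundle, truth, results


@pytest.fixture(scope="session")
def monthly_fit():
    """Default full-grid study (3 fractions, 270 samples) with one network
    per month."""
    config = SimConfig(seed=1)
    bundle, truth = simulate_bundle(config)
    results = CooccurrenceNetwork(bundle).fit(seed=1)
    return bundle, truth, results


@pytest.fixture
def toy_counts():
    counts = pd.DataFrame(
        [[10, 0, 3], [5, 5, 5], [0, 1, 0]],
        index=["OTU_a", "OTU_b", "OTU_c"],
        columns=["s1", "s2", "s3"],
    )
    return OtuTable(counts)


@pytest.fixture
def toy_network():
    g = nx.Graph(month="Jul")
    g.add_edge("a", "b", rho=0.9, q=0.001, sign="positive")
    g.add_edge("b", "c", rho=-0.8, q=0.002, sign="negative")
    g.nodes["a"].update(kind="otu", fraction="FL")
    g.nodes["b"].update(kind="otu", fraction="FL")
    g.nodes["c"].update(kind="env")
    return g
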