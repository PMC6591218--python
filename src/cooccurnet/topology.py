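"""Network-level topology: Table-style summaries against Erdős–Rényi nulls.

The null model is G(n, m) — a uniform draw over simple graphs with exactly
the observed node and edge counts — honouring the "same numbers of nodes
and edges" comparison.  Average shortest path length and diameter are
computed on the largest connected component (the monthly networks are
multi-component); the clustering coefficient averages local clustering
over *all* nodes, with degree < 2 nodes contributing 0.  The small-world
coefficient is sigma = (CC/CCr) / (APL/APLr), computed from unrounded
internal values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cooccurnet")


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def density(network: nx.Graph) -> float:
    """2E / (N(N-1)) over the network's node set."""
    n = network.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * network.number_of_edges() / (n * (n - 1))


def average_degree(network: nx.Graph) -> float:
    """2E / N."""
    n = network.number_of_nodes()
    if n == 0:
        return 0.0
    return 2.0 * network.number_of_edges() / n


def clustering_coefficient(network: nx.Graph) -> float:
    """Mean local clustering over all nodes (degree < 2 contributes 0)."""
    if network.number_of_nodes() == 0:
        return 0.0
    return nx.average_clustering(network)


def _largest_component(network: nx.Graph) -> nx.Graph:
    if network.number_of_nodes() == 0:
        return network
    comp = max(nx.connected_components(network), key=len)
    if len(comp) < network.number_of_nodes():
        logger.debug("APL/diameter computed on largest component "
                     "(%d of %d nodes)", len(comp),
                     network.number_of_nodes())
    return network.subgraph(comp)


def apl(network: nx.Graph) -> float:
    """Average shortest path length on the largest connected component."""
    g = _largest_component(network)
    if g.number_of_nodes() < 2:
        return 0.0
    return nx.average_shortest_path_length(g)


def diameter(network: nx.Graph) -> int:
    """Longest shortest path on the largest connected component."""
    g = _largest_component(network)
    if g.number_of_nodes() < 2:
        return 0
    return nx.diameter(g)


# ---------------------------------------------------------------------------
# Erdős–Rényi null ensemble
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Per-replicate metrics of a G(n, m) ensemble."""

    n: int
    m: int
    seed: int
    cc: np.ndarray
    apl: np.ndarray
    modularity: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.cc.size

    def mean(self, metric: str) -> float:
        return float(getattr(self, metric).mean())

    def sd(self, metric: str) -> float:
        return float(getattr(self, metric).std(ddof=1))

    def se(self, metric: str) -> float:
        return self.sd(metric) / math.sqrt(self.n_reps)


def er_null(n: int, m: int, n_reps: int = 100, seed: int = 0) -> NullEnsemble:
    """Ensemble of uniform G(n, m) random graphs with per-replicate CC,
    APL (largest component) and Louvain modularity."""
    from .roles import louvain_partition

    if m > n * (n - 1) // 2:
        raise ValueError(f"m={m} exceeds the {n * (n - 1) // 2} possible edges")
    rng = np.random.default_rng([3, int(seed)])
    cc = np.empty(n_reps)
    apl_ = np.empty(n_reps)
    mod = np.empty(n_reps)
    for i in range(n_reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        cc[i] = clustering_coefficient(g)
        apl_[i] = apl(g)
        if g.number_of_edges() == 0:
            mod[i] = 0.0
        else:
            part = louvain_partition(g, seed=int(rng.integers(2 ** 31)),
                                     n_restarts=1)
            mod[i] = part.modularity
    return NullEnsemble(n=n, m=m, seed=seed, cc=cc, apl=apl_, modularity=mod)


class SmallWorld(NamedTuple):
    sigma: float
    cc_ratio: float
    apl_ratio: float


def small_world_sigma(cc: float, cc_random: float,
                      apl_value: float, apl_random: float) -> SmallWorld:
    """sigma = (CC/CCr) / (APL/APLr), with the two ratios."""
    cc_ratio = cc / cc_random if cc_random else float("nan")
    apl_ratio = apl_value / apl_random if apl_random else float("nan")
    sigma = cc_ratio / apl_ratio if apl_ratio else float("nan")
    return SmallWorld(sigma=sigma, cc_ratio=cc_ratio, apl_ratio=apl_ratio)


# ---------------------------------------------------------------------------
# degree-distribution statistics
# ---------------------------------------------------------------------------

def degree_powerlaw_r2(network: nx.Graph) -> float:
    """R² of the OLS fit of log10 degree frequency on log10 degree
    (k >= 1, raw frequencies, no binning).  Degenerate distributions
    (fewer than 3 distinct degrees) give NaN with a warning."""
    degrees = np.array([d for _, d in network.degree() if d >= 1])
    if degrees.size == 0:
        logger.warning("no nodes with degree >= 1; R^2 undefined")
        return float("nan")
    ks, freq = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        logger.warning("degree distribution has %d distinct values; "
                       "R^2 undefined", ks.size)
        return float("nan")
    fit = stats.linregress(np.log10(ks), np.log10(freq))
    return float(fit.rvalue ** 2)


def degree_concentration(network: nx.Graph, top_frac: float = 0.1) -> float:
    """Share of edges incident to at least one of the top ``top_frac``
    highest-degree nodes (ties broken by node id)."""
    n = network.number_of_nodes()
    m = network.number_of_edges()
    if m == 0:
        logger.warning("empty network: degree concentration set to 0")
        return 0.0
    k = math.ceil(top_frac * n)
    ranked = sorted(network.degree(), key=lambda t: (-t[1], str(t[0])))
    top = {node for node, _ in ranked[:k]}
    hit = sum(1 for u, v in network.edges() if u in top or v in top)
    return hit / m


def edge_composition(network: nx.Graph) -> dict:
    """Taxonomic / structural edge composition.

    Returns a dict with

    - ``phylum_matrix``: symmetric phylum × phylum edge-count proportion
      matrix (OTU–OTU edges with phylum annotations on both ends);
    - ``fraction_ratio``: per-fraction edges/nodes ratio, a fraction's
      edges being those with both endpoints in it;
    - ``env_taxon``: edge counts between environmental variables and each
      phylum (empty when there are no env nodes).
    """
    phylum_pairs: dict[tuple[str, str], int] = {}
    env_taxon: dict[str, int] = {}
    frac_nodes: dict[str, int] = {}
    frac_edges: dict[str, int] = {}
    for node, d in network.nodes(data=True):
        frac = d.get("fraction")
        if frac:
            frac_nodes[frac] = frac_nodes.get(frac, 0) + 1
    for u, v, d in network.edges(data=True):
        du, dv = network.nodes[u], network.nodes[v]
        ku, kv = du.get("kind"), dv.get("kind")
        pu, pv = du.get("phylum"), dv.get("phylum")
        if ku == "otu" and kv == "otu" and pu and pv:
            key = tuple(sorted((pu, pv)))
            phylum_pairs[key] = phylum_pairs.get(key, 0) + 1
        if {ku, kv} == {"otu", "env"}:
            phyl = pu if ku == "otu" else pv
            if phyl:
                env_taxon[phyl] = env_taxon.get(phyl, 0) + 1
        fu, fv = du.get("fraction"), dv.get("fraction")
        if fu and fu == fv:
            frac_edges[fu] = frac_edges.get(fu, 0) + 1

    phyla = sorted({p for pair in phylum_pairs for p in pair})
    mat = pd.DataFrame(0.0, index=phyla, columns=phyla)
    total = sum(phylum_pairs.values())
    for (a, b), cnt in phylum_pairs.items():
        share = cnt / total
        mat.loc[a, b] = mat.loc[b, a] = share
    ratios = pd.Series({
        f: frac_edges.get(f, 0) / frac_nodes[f]
        for f in sorted(frac_nodes)
    }, dtype=float)
    return {
        "phylum_matrix": mat,
        "fraction_ratio": ratios,
        "env_taxon": pd.Series(env_taxon, dtype=float).sort_index(),
    }


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

#: Row labels of the per-month topology report, in print order.
SUMMARY_ROWS = (
    ("Nodes", "nodes"),
    ("Edges", "edges"),
    ("Diameter", "diameter"),
    ("Network density", "density"),
    ("Average node degree", "average_degree"),
    ("Modularity", "modularity"),
    ("Modularity, random", "modularity_random"),
    ("Clustering coefficient (CC)", "cc"),
    ("Clustering coefficient, random (CCr)", "cc_random"),
    ("Ratio of CC/CCr", "cc_ratio"),
    ("Average shortest path length (APL)", "apl"),
    ("Average shortest path length, random (APLr)", "apl_random"),
    ("Ratio of APL/APLr", "apl_ratio"),
    ("Small-word coefficient σ, (CC/CCr)/(APL/APLr)", "sigma"),
)


@dataclass
class TopologySummary:
    """Observed vs G(n, m)-null topology of one network."""

    nodes: int
    edges: int
    diameter: int
    density: float
    average_degree: float
    modularity: float
    modularity_random: float
    cc: float
    cc_random: float
    apl: float
    apl_random: float
    null_seed: int = 0
    null_reps: int = 100

    @property
    def cc_ratio(self) -> float:
        return self.cc / self.cc_random if self.cc_random else float("nan")

    @property
    def apl_ratio(self) -> float:
        return self.apl / self.apl_random if self.apl_random else float("nan")

    @property
    def sigma(self) -> float:
        return small_world_sigma(self.cc, self.cc_random,
                                 self.apl, self.apl_random).sigma

    def as_series(self, label: str = "network") -> pd.Series:
        return pd.Series({row: getattr(self, attr)
                          for row, attr in SUMMARY_ROWS}, name=label)


def summarize_topology(
    network: nx.Graph,
    n_reps: int = 100,
    seed: int = 0,
    partition=None,
) -> TopologySummary:
    """Full observed-vs-null topology summary of one network."""
    from .roles import louvain_partition

    n = network.number_of_nodes()
    m = network.number_of_edges()
    if partition is None and m > 0:
        partition = louvain_partition(network, seed=seed)
    ens = er_null(n, m, n_reps=n_reps, seed=seed) if m > 0 else None
    return TopologySummary(
        nodes=n,
        edges=m,
        diameter=diameter(network),
        density=density(network),
        average_degree=average_degree(network),
        modularity=partition.modularity if partition else float("nan"),
        modularity_random=ens.mean("modularity") if ens else float("nan"),
        cc=clustering_coefficient(network),
        cc_random=ens.mean("cc") if ens else float("nan"),
        apl=apl(network),
        apl_random=ens.mean("apl") if ens else float("nan"),
        null_seed=seed,
        null_reps=n_reps,
    )


def topology_report(summaries: dict[str, TopologySummary]) -> pd.DataFrame:
    """Report table: one column per network, canonical row labels."""
    return pd.DataFrame({label: s.as_series(label)
                         for label, s in summaries.items()})
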