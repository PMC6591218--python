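"""Module detection, Guimerà–Amaral node roles, module depth preferences
and the recurrence network across months.

Roles partition the (Z, C) plane at Z = 1.5 and C = 0.62:

====================  =====================
module hub            Z > 1.5 and C <= 0.62
network hub           Z > 1.5 and C > 0.62
connector             Z <= 1.5 and C > 0.62
peripheral            Z <= 1.5 and C <= 0.62
====================  =====================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tables import DEPTHS

logger = logging.getLogger("cooccurnet")

Z_THRESHOLD = 1.5
C_THRESHOLD = 0.62

ROLES = ("peripheral", "connector", "module hub", "network hub")


@dataclass
class ModulePartition:
    """A node → module assignment with its modularity score."""

    membership: dict
    modularity: float
    seed: int
    resolution: float = 1.0

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.membership.values()))

    def members(self, module: int) -> list:
        return [n for n, m in self.membership.items() if m == module]

    def as_series(self) -> pd.Series:
        return pd.Series(self.membership, name="module")


def louvain_partition(
    network: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 10,
) -> ModulePartition:
    """Louvain modularity maximization; best of ``n_restarts`` seeded runs.

    Ties in the greedy optimization are broken by the seeded random node
    order, so the partition is reproducible for a given seed.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    best_comms, best_q = None, -np.inf
    for k in range(n_restarts):
        comms = nx.community.louvain_communities(
            network, seed=seed + k, resolution=resolution, weight=None)
        q = nx.community.modularity(network, comms, weight=None,
                                    resolution=resolution)
        if q > best_q:
            best_comms, best_q = comms, q
    membership = {}
    for idx, comm in enumerate(sorted(best_comms, key=lambda c: -len(c)),
                               start=1):
        for node in comm:
            membership[node] = idx
    return ModulePartition(membership=membership, modularity=float(best_q),
                           seed=seed, resolution=resolution)


# ---------------------------------------------------------------------------
# Z / C node statistics
# ---------------------------------------------------------------------------

def within_module_degree_z(
    network: nx.Graph, partition: ModulePartition
) -> pd.Series:
    """Within-module degree z-score.

    Z_i = (kappa_i - mu_s) / sigma_s, where kappa_i counts the links of
    node i inside its own module s and mu_s, sigma_s are the mean and
    (population) standard deviation of kappa over s's members.
    sigma_s = 0 (including singleton modules) gives Z_i = 0.
    """
    members = {m: partition.members(m) for m in partition.modules}
    z = {}
    for module, nodes in members.items():
        node_set = set(nodes)
        kappa = np.array([
            sum(1 for nb in network.neighbors(n) if nb in node_set)
            for n in nodes
        ], dtype=float)
        sd = kappa.std()
        if sd == 0:
            for n in nodes:
                z[n] = 0.0
        else:
            mu = kappa.mean()
            for n, k in zip(nodes, kappa):
                z[n] = (k - mu) / sd
    return pd.Series(z, name="Z")


def participation_coefficient(
    network: nx.Graph, partition: ModulePartition
) -> pd.Series:
    """Among-module connectivity C_i = 1 - sum_t (kappa_it / k_i)^2.

    0 when all links are internal; approaches 1 as links spread evenly
    over modules.  Degree-0 nodes get C = 0.
    """
    c = {}
    for node in network.nodes:
        k = network.degree(node)
        if k == 0:
            c[node] = 0.0
            continue
        per_module: dict[int, int] = {}
        for nb in network.neighbors(node):
            t = partition.membership[nb]
            per_module[t] = per_module.get(t, 0) + 1
        c[node] = 1.0 - sum((kt / k) ** 2 for kt in per_module.values())
    return pd.Series(c, name="C")


def classify_role(z: float, c: float) -> str:
    """Node role from its (Z, C) coordinates; boundaries inclusive on the
    <= side, so (1.5, 0.62) is peripheral."""
    if z > Z_THRESHOLD:
        return "module hub" if c <= C_THRESHOLD else "network hub"
    return "peripheral" if c <= C_THRESHOLD else "connector"


def node_roles(
    network: nx.Graph, partition: ModulePartition | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-node module, Z, C, role and degree for one network."""
    if partition is None:
        partition = louvain_partition(network, seed=seed)
    z = within_module_degree_z(network, partition)
    c = participation_coefficient(network, partition)
    df = pd.DataFrame({
        "module": partition.as_series(),
        "Z": z,
        "C": c,
        "degree": pd.Series(dict(network.degree()), dtype=float),
    })
    df["role"] = [classify_role(zi, ci) for zi, ci in zip(df["Z"], df["C"])]
    for attr in ("kind", "fraction", "phylum", "order", "family"):
        vals = nx.get_node_attributes(network, attr)
        if vals:
            df[attr] = pd.Series(vals)
    return df


# ---------------------------------------------------------------------------
# module depth preference
# ---------------------------------------------------------------------------

def module_depth_profile(
    partition: ModulePartition,
    otu_table,
    meta: pd.DataFrame,
    surface_min: float = 0.5,
    deep_min: float = 0.75,
) -> pd.DataFrame:
    """Depth-layer abundance profile and S / MB / W label per module.

    For each module, member-OTU relative abundances are averaged within
    each depth layer (each OTU within its own size fraction's samples) and
    the three layer means are normalized to sum 1.  Labels: S when
    f_surface >= ``surface_min``; MB when f_middle + f_bottom >=
    ``deep_min``; W otherwise.  Modules without OTU members (environment
    or phytoplankton only) are labeled "n/a".
    """
    from .diversity import relative_abundance

    rel = relative_abundance(otu_table.counts)
    rows = {}
    for module in partition.modules:
        shares = np.zeros(len(DEPTHS))
        n_members = 0
        for node in partition.members(module):
            otu, frac = _split_variable(node)
            if otu is None or otu not in rel.index:
                continue
            samples = meta.index[meta["fraction"] == frac] if frac else meta.index
            vals = rel.loc[otu, samples]
            depth_means = vals.groupby(meta.loc[samples, "depth"]).mean()
            shares += np.array([depth_means.get(d, 0.0) for d in DEPTHS])
            n_members += 1
        if n_members == 0 or shares.sum() == 0:
            rows[module] = {"f_surface": np.nan, "f_middle": np.nan,
                            "f_bottom": np.nan, "label": "n/a",
                            "n_otus": n_members}
            continue
        shares = shares / shares.sum()
        f_surface, f_middle, f_bottom = shares
        if f_surface >= surface_min:
            label = "S"
        elif f_middle + f_bottom >= deep_min:
            label = "MB"
        else:
            label = "W"
        rows[module] = {"f_surface": f_surface, "f_middle": f_middle,
                        "f_bottom": f_bottom, "label": label,
                        "n_otus": n_members}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def _split_variable(node) -> tuple[str | None, str | None]:
    """Map a network node id back to (otu_id, fraction); non-OTU nodes
    give (None, None)."""
    s = str(node)
    if s.startswith("phyto:"):
        return None, None
    if "|" in s:
        otu, frac = s.rsplit("|", 1)
        return otu, frac
    if s.startswith("OTU"):
        return s, None
    return None, None


# ---------------------------------------------------------------------------
# recurrence network
# ---------------------------------------------------------------------------

def recurrence_network(
    monthly: list[nx.Graph] | list[tuple[str, nx.Graph]],
    min_occurrence: int = 3,
    strict_greater: bool = False,
) -> nx.Graph:
    """Network of variable pairs whose correlation recurs across months.

    Edge identity is the unordered variable pair; its occurrence is the
    number of monthly networks containing it.  Pairs with occurrence >=
    ``min_occurrence`` (strictly > when ``strict_greater``) are retained
    with the months present, the mean rho, and a sign-consistency flag.
    Node attribute ``mean_degree`` is the node's mean degree over the
    monthly networks in which it appears.  The result does not depend on
    the order of the input list.
    """
    graphs: list[tuple[str, nx.Graph]] = []
    for item in monthly:
        if isinstance(item, tuple):
            graphs.append(item)
        else:
            graphs.append((item.graph.get("month", "?"), item))
    if len(graphs) < min_occurrence:
        raise ValueError(
            f"need at least {min_occurrence} monthly networks, "
            f"got {len(graphs)}")

    seen: dict[tuple, dict] = {}
    for month, g in graphs:
        for u, v, d in g.edges(data=True):
            key = tuple(sorted((str(u), str(v))))
            rec = seen.setdefault(key, {"months": [], "rhos": []})
            rec["months"].append(month)
            rec["rhos"].append(d.get("rho", np.nan))

    out = nx.Graph(min_occurrence=min_occurrence)
    for (u, v), rec in sorted(seen.items()):
        count = len(rec["months"])
        keep = count > min_occurrence if strict_greater else count >= min_occurrence
        if not keep:
            continue
        rhos = np.asarray(rec["rhos"], dtype=float)
        signs = np.sign(rhos[~np.isnan(rhos)])
        out.add_edge(
            u, v,
            occurrence=count,
            months=",".join(sorted(rec["months"])),
            mean_rho=float(np.nanmean(rhos)),
            sign_consistent=bool(signs.size and (signs == signs[0]).all()),
        )
    # mean degree over the monthly networks where the node appears
    for node in out.nodes:
        degs = [g.degree(node) for _, g in graphs if node in g]
        out.nodes[node]["mean_degree"] = float(np.mean(degs)) if degs else 0.0
        for _, g in graphs:
            if node in g:
                for key, val in g.nodes[node].items():
                    out.nodes[node].setdefault(key, val)
                break
    return out
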