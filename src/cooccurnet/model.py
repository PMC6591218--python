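"""Model/Results interface over the co-occurrence network pipeline.

:class:`CooccurrenceNetwork` is constructed from the study tables (counts,
sample metadata, environment, optional phytoplankton and taxonomy) plus an
edge-retention policy; :meth:`CooccurrenceNetwork.fit` runs
filter → Spearman → FDR → threshold and returns a
:class:`CooccurrenceNetworkResults` carrying the monthly networks and the
derived quantities: Table-style topology summaries against Erdős–Rényi
nulls, Louvain partitions, Z/C node roles, module depth preferences and
the recurrence network.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from . import correlation, roles, topology
from .correlation import ThresholdPolicy
from .simulate import SimConfig, simulate_bundle
from .tables import AnalysisBundle, OtuTable, join_tables

logger = logging.getLogger("cooccurnet")


class CooccurrenceNetwork:
    """Correlation-network model of a size-fractionated community survey.

    Parameters
    ----------
    bundle
        Aligned study tables (see :func:`cooccurnet.tables.join_tables`).
    policy
        Edge-retention thresholds; defaults to Q < 0.01 (0.05 for
        October) and |rho| >= 0.7.
    max_relabund_min, prevalence_min
        The per-fraction OTU screen applied before correlation.
    pooled
        If True, correlate over the whole sample grid instead of building
        one network per month.
    """

    def __init__(
        self,
        bundle: AnalysisBundle,
        policy: ThresholdPolicy | None = None,
        max_relabund_min: float = 0.001,
        prevalence_min: float = 0.7,
        pooled: bool = False,
    ):
        self.bundle = bundle
        self.policy = policy or ThresholdPolicy()
        self.max_relabund_min = max_relabund_min
        self.prevalence_min = prevalence_min
        self.pooled = pooled

    @classmethod
    def from_tables(cls, counts, meta, env=None, phyto=None, taxonomy=None,
                    **kwargs) -> "CooccurrenceNetwork":
        """Build from raw DataFrames; samples are aligned on the common
        id set."""
        otu = counts if isinstance(counts, OtuTable) else OtuTable(counts)
        bundle = join_tables(otu, meta, env=env, phyto=phyto,
                             taxonomy=taxonomy)
        return cls(bundle, **kwargs)

    @classmethod
    def from_simulation(cls, config: SimConfig | None = None,
                        seed: int | None = None, **kwargs):
        """Build from the synthetic generator.  Returns (model, truth)."""
        config = config or SimConfig()
        bundle, truth = simulate_bundle(config, seed=seed)
        return cls(bundle, **kwargs), truth

    def fit(self, seed: int = 0) -> "CooccurrenceNetworkResults":
        """Infer the thresholded network(s) and return the results."""
        if self.pooled:
            g = correlation.network_for_month(
                self.bundle, self.policy, month=None,
                max_relabund_min=self.max_relabund_min,
                prevalence_min=self.prevalence_min)
            networks = {"pooled": g}
        else:
            networks = dict(correlation.monthly_networks(
                self.bundle, self.policy,
                max_relabund_min=self.max_relabund_min,
                prevalence_min=self.prevalence_min))
        return CooccurrenceNetworkResults(self, networks, seed=seed)


class CooccurrenceNetworkResults:
    """Fitted co-occurrence networks and their derived statistics."""

    def __init__(self, model: CooccurrenceNetwork,
                 networks: dict[str, nx.Graph], seed: int = 0):
        self.model = model
        self.networks = networks
        self.seed = seed
        self._partitions: dict[str, roles.ModulePartition] = {}

    # -- modules & roles ----------------------------------------------------

    def partition(self, label: str) -> roles.ModulePartition:
        """Louvain partition of one network (cached)."""
        if label not in self._partitions:
            g = self.networks[label]
            self._partitions[label] = roles.louvain_partition(
                g, seed=self.seed)
        return self._partitions[label]

    def node_roles(self, label: str | None = None) -> pd.DataFrame:
        """Z/C/role table; one network, or all networks stacked with a
        ``network`` column plus a pooled unique-variable summary flag."""
        labels = [label] if label else [
            lb for lb, g in self.networks.items() if g.number_of_edges()]
        frames = []
        for lb in labels:
            df = roles.node_roles(self.networks[lb], self.partition(lb))
            df.insert(0, "network", lb)
            frames.append(df)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames)

    def module_hubs(self, dedupe: bool = True) -> pd.DataFrame:
        """All module-hub nodes across networks; by default one row per
        unique variable (its maximum-Z occurrence)."""
        df = self.node_roles()
        hubs = df[df["role"] == "module hub"].copy()
        if dedupe and not hubs.empty:
            hubs = (hubs.sort_values("Z", ascending=False)
                        .groupby(hubs.index).first())
        return hubs

    def module_depth_profiles(self, label: str) -> pd.DataFrame:
        """S / MB / W depth-preference classification of one network's
        modules."""
        return roles.module_depth_profile(
            self.partition(label), self.model.bundle.otu,
            self.model.bundle.meta)

    # -- topology -----------------------------------------------------------

    def topology_summary(self, label: str, n_reps: int = 100,
                         seed: int | None = None) -> topology.TopologySummary:
        g = self.networks[label]
        return topology.summarize_topology(
            g, n_reps=n_reps, seed=self.seed if seed is None else seed,
            partition=self.partition(label) if g.number_of_edges() else None)

    def topology_report(self, n_reps: int = 100) -> pd.DataFrame:
        """Observed-vs-null topology table, one column per network."""
        summaries = {lb: self.topology_summary(lb, n_reps=n_reps)
                     for lb in self.networks}
        return topology.topology_report(summaries)

    # -- recurrence ---------------------------------------------------------

    def recurrence_network(self, min_occurrence: int = 3,
                           strict_greater: bool = False) -> nx.Graph:
        """Pairs whose correlation recurs in >= ``min_occurrence`` monthly
        networks."""
        return roles.recurrence_network(
            list(self.networks.items()), min_occurrence=min_occurrence,
            strict_greater=strict_greater)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted networks."""
        pol = self.model.policy
        lines = [
            "Co-occurrence network results",
            "=" * 29,
            f"Samples: {len(self.model.bundle.sample_ids)}   "
            f"OTUs: {self.model.bundle.otu.shape[0]}",
            f"Thresholds: Q < {pol.q_max:g} "
            f"(overrides: {pol.month_q_max or 'none'}), "
            f"|rho| >= {pol.rho_min:g}"
            + (" (positive only)" if pol.positive_only else ""),
            "",
            f"{'network':<10}{'nodes':>8}{'edges':>8}{'modularity':>12}",
        ]
        for lb, g in self.networks.items():
            if g.number_of_edges():
                q = self.partition(lb).modularity
                lines.append(f"{lb:<10}{g.number_of_nodes():>8}"
                             f"{g.number_of_edges():>8}{q:>12.3f}")
            else:
                lines.append(f"{lb:<10}{0:>8}{0:>8}{'-':>12}")
        return "\n".join(lines)

    def plot_roles(self, label: str | None = None, ax=None):
        """Z–C scatter with the role-threshold lines."""
        import matplotlib.pyplot as plt

        df = self.node_roles(label)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for role, marker in (("peripheral", "."), ("connector", "s"),
                             ("module hub", "^"), ("network hub", "*")):
            sub = df[df["role"] == role]
            if not sub.empty:
                ax.scatter(sub["C"], sub["Z"], marker=marker, label=role,
                           s=20 + 2 * sub["degree"])
        ax.axhline(roles.Z_THRESHOLD, ls="--", lw=0.8, color="grey")
        ax.axvline(roles.C_THRESHOLD, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("Among-module connectivity (C)")
        ax.set_ylabel("Within-module degree (Z)")
        ax.legend(fontsize=8)
        return ax
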