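import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cooccurnet.roles import (ModulePartition, classify_role,
                              louvain_partition, module_depth_profile,
                              node_roles, participation_coefficient,
                              recurrence_network, within_module_degree_z)
from cooccurnet.tables import OtuTable


class TestLouvain:
    def test_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        part = louvain_partition(g, seed=0)
        assert len(part.modules) == 2
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        part = louvain_partition(nx.complete_graph(6), seed=0)
        assert len(part.modules) == 1
        assert part.modularity == pytest.approx(0.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            louvain_partition(nx.Graph())

    def test_reproducible(self):
        g = nx.gnm_random_graph(40, 100, seed=1)
        p1 = louvain_partition(g, seed=5)
        p2 = louvain_partition(g, seed=5)
        assert p1.membership == p2.membership

    def test_planted_modules_recovered(self, strong_fit):
        from sklearn.metrics import adjusted_rand_score
        _, truth, results = strong_fit
        g = results.networks["pooled"]
        part = results.partition("pooled")
        otus = [n for n in g.nodes if str(n).startswith("OTU")]
        true = [truth.module_of_otu.get(str(n).split("|")[0], -1)
                for n in otus]
        pred = [part.membership[n] for n in otus]
        assert adjusted_rand_score(true, pred) >= 0.8


def _partition(g, groups):
    membership = {}
    for idx, group in enumerate(groups, start=1):
        for n in group:
            membership[n] = idx
    return ModulePartition(membership=membership, modularity=0.0, seed=0)


class TestZScore:
    def test_equal_internal_degree_gives_zero(self):
        g = nx.complete_graph(4)
        z = within_module_degree_z(g, _partition(g, [range(4)]))
        assert (z == 0).all()

    def test_star_module_hand_value(self):
        g = nx.star_graph(3)  # hub 0, leaves 1..3; kappa = (3,1,1,1)
        z = within_module_degree_z(g, _partition(g, [range(4)]))
        assert z[0] == pytest.approx((3 - 1.5) / np.std([3, 1, 1, 1]))
        assert z[0] == pytest.approx(1.7320508, abs=1e-6)

    def test_singleton_module_zero(self):
        g = nx.path_graph(2)
        z = within_module_degree_z(g, _partition(g, [[0], [1]]))
        assert z[0] == 0.0 and z[1] == 0.0

    def test_standardization_within_modules(self, strong_fit):
        _, _, results = strong_fit
        g = results.networks["pooled"]
        part = results.partition("pooled")
        z = within_module_degree_z(g, part)
        for module in part.modules:
            vals = z[part.members(module)]
            if vals.std() > 0:  # sigma_s > 0 modules are standardized
                assert vals.mean() == pytest.approx(0.0, abs=1e-9)
                assert vals.to_numpy().std() == pytest.approx(1.0, abs=1e-9)


class TestParticipationCoefficient:
    def test_all_internal_links(self):
        g = nx.complete_graph(5)
        c = participation_coefficient(g, _partition(g, [range(5)]))
        assert (c == 0).all()

    def test_even_split_four_modules(self):
        g = nx.star_graph(4)  # center 0 with 4 leaves
        part = _partition(g, [[0, 1], [2], [3], [4]])
        c = participation_coefficient(g, part)
        assert c[0] == pytest.approx(0.75)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_even_split_limit(self, m):
        g = nx.star_graph(m)
        part = _partition(g, [[0]] + [[i] for i in range(1, m + 1)])
        # center's m links spread evenly over m other modules
        c = participation_coefficient(g, part)
        assert c[0] == pytest.approx(1 - 1 / m)

    def test_bounded_by_module_count(self, strong_fit):
        _, _, results = strong_fit
        g = results.networks["pooled"]
        part = results.partition("pooled")
        c = participation_coefficient(g, part)
        t = len(part.modules)
        assert (c <= 1 - 1 / t + 1e-12).all()
        assert (c >= 0).all()

    def test_degree_conservation(self, strong_fit):
        _, _, results = strong_fit
        g = results.networks["pooled"]
        part = results.partition("pooled")
        internal_deg_total = 0
        internal_edges = 0
        for u, v in g.edges():
            if part.membership[u] == part.membership[v]:
                internal_edges += 1
        for module in part.modules:
            members = set(part.members(module))
            for n in members:
                internal_deg_total += sum(
                    1 for nb in g.neighbors(n) if nb in members)
        assert internal_deg_total == 2 * internal_edges


class TestClassifyRole:
    @pytest.mark.parametrize("z,c,expected", [
        (2.0, 0.30, "module hub"),
        (1.5, 0.62, "peripheral"),   # both boundaries inclusive on <=
        (0.0, 0.90, "connector"),
        (2.0, 0.70, "network hub"),
        (1.51, 0.62, "module hub"),
    ])
    def test_examples(self, z, c, expected):
        assert classify_role(z, c) == expected

    def test_plane_is_partitioned(self):
        roles = {classify_role(z, c)
                 for z in np.linspace(-2, 4, 25)
                 for c in np.linspace(0, 1, 25)}
        assert roles == {"peripheral", "connector", "module hub",
                         "network hub"}
        # every grid point got exactly one (string) role by construction
        for z, c in itertools.product([-1, 1.5, 1.6], [0.3, 0.62, 0.7]):
            assert isinstance(classify_role(z, c), str)

    def test_planted_hubs_score_high(self, strong_fit):
        _, truth, results = strong_fit
        df = results.node_roles("pooled")
        hub_rows = df.reindex([f"{h}|FL" for h in sorted(truth.hub_flags)])
        assert (hub_rows["Z"] > 1.5).all()


class TestModuleDepthProfile:
    def _meta(self):
        rows = []
        for depth in ("surface", "middle", "bottom"):
            for i in range(2):
                rows.append((f"{depth}{i}", "Jul", "ST1", depth, "FL"))
        return pd.DataFrame(
            rows, columns=["sample_id", "month", "station", "depth",
                           "fraction"]).set_index("sample_id")

    def _profile(self, per_depth, total=1000):
        # filler OTU tops every sample up to the same total, so the focal
        # OTU's relative abundance equals per_depth/total exactly
        part = ModulePartition({"OTU_1|FL": 1, "other": 1}, 0.0, 0)
        meta = self._meta()
        counts = pd.DataFrame(
            {sid: [per_depth[meta.loc[sid, "depth"]],
                   total - per_depth[meta.loc[sid, "depth"]]]
             for sid in meta.index},
            index=["OTU_1", "OTU_2"])
        return module_depth_profile(part, OtuTable(counts), meta)

    def test_surface_only_module_is_S(self):
        prof = self._profile({"surface": 500, "middle": 0, "bottom": 0})
        assert prof.loc[1, "label"] == "S"
        assert prof.loc[1, "f_surface"] == pytest.approx(1.0)

    def test_uniform_module_is_W(self):
        prof = self._profile({"surface": 500, "middle": 500, "bottom": 500})
        assert prof.loc[1, "label"] == "W"

    def test_deep_biased_module_is_MB(self):
        # shares approximately (0.1, 0.4, 0.5)
        prof = self._profile({"surface": 100, "middle": 400, "bottom": 500})
        assert prof.loc[1, "label"] == "MB"
        assert prof.loc[1, "f_bottom"] == pytest.approx(0.5, abs=0.02)

    def test_env_only_module_is_na(self):
        g = nx.Graph()
        part = ModulePartition({"temperature": 1, "salinity": 1}, 0.0, 0)
        meta = self._meta()
        counts = pd.DataFrame({sid: [10] for sid in meta.index},
                              index=["OTU_1"])
        prof = module_depth_profile(part, OtuTable(counts), meta)
        assert prof.loc[1, "label"] == "n/a"

    def test_raised_depth_effect_orders_profiles(self):
        """With a strong depth term in the factor, S-modules peak at the
        surface and MB-modules in middle+bottom layers."""
        from cooccurnet import CooccurrenceNetwork, SimConfig
        from cooccurnet.simulate import simulate_bundle
        cfg = SimConfig.strong_signal(seed=2, depth_effect=3.0)
        bundle, truth = simulate_bundle(cfg)
        results = CooccurrenceNetwork(bundle, pooled=True).fit(seed=2)
        part = results.partition("pooled")
        prof = results.module_depth_profiles("pooled")
        # map fitted modules to planted ones via the hub they contain
        checked = 0
        for module in part.modules:
            hubs = [n for n in part.members(module)
                    if str(n).split("|")[0] in truth.hub_flags]
            if len(hubs) != 1 or prof.loc[module, "label"] == "n/a":
                continue
            pref = truth.depth_preference_of_module[
                truth.module_of_otu[str(hubs[0]).split("|")[0]]]
            row = prof.loc[module]
            if pref == "S":
                assert row["f_surface"] == row[
                    ["f_surface", "f_middle", "f_bottom"]].max()
                checked += 1
            elif pref == "MB":
                assert row["f_middle"] + row["f_bottom"] > 2 * row["f_surface"]
                checked += 1
        assert checked >= 2


class TestRecurrenceNetwork:
    def _monthly(self):
        months = ["Jul", "Aug", "Sept", "Oct", "Dec"]
        graphs = []
        for i, month in enumerate(months):
            g = nx.Graph(month=month)
            g.add_edge("a", "b", rho=0.8)               # all 5 months
            if month in ("Jul", "Aug", "Sept"):
                g.add_edge("c", "d", rho=0.75)          # 3 months
            if month in ("Jul", "Aug"):
                g.add_edge("e", "f", rho=-0.9)          # only 2 months
            graphs.append((month, g))
        return graphs

    def test_occurrence_counting(self):
        rec = recurrence_network(self._monthly())
        assert rec.edges["a", "b"]["occurrence"] == 5
        assert rec.edges["c", "d"]["occurrence"] == 3
        assert not rec.has_edge("e", "f")

    def test_months_and_sign_recorded(self):
        rec = recurrence_network(self._monthly())
        assert set(rec.edges["c", "d"]["months"].split(",")) == \
            {"Jul", "Aug", "Sept"}
        assert rec.edges["a", "b"]["sign_consistent"]

    def test_strict_greater_mode(self):
        rec = recurrence_network(self._monthly(), strict_greater=True)
        assert rec.has_edge("a", "b")
        assert not rec.has_edge("c", "d")

    def test_mean_degree_attribute(self):
        rec = recurrence_network(self._monthly())
        # "a" has degree 1 in each of the 5 monthly networks
        assert rec.nodes["a"]["mean_degree"] == pytest.approx(1.0)

    def test_order_invariance(self):
        graphs = self._monthly()
        rec1 = recurrence_network(graphs)
        rec2 = recurrence_network(list(reversed(graphs)))
        assert set(rec1.edges) == set(rec2.edges)
        for e in rec1.edges:
            assert rec1.edges[e] == rec2.edges[e]

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError):
            recurrence_network(self._monthly()[:2], min_occurrence=3)


def test_node_roles_table(strong_fit):
    _, _, results = strong_fit
    df = results.node_roles("pooled")
    assert {"module", "Z", "C", "role", "degree"} <= set(df.columns)
    assert df["role"].isin(["peripheral", "connector", "module hub",
                            "network hub"]).all()
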