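"""Co-occurrence network construction, edge signs, topology statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import paddyflux as pf
from paddyflux.mic import NetworkConfig


def _table(rows: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"S{i}" for i in range(n)]).T


class TestBuildNetwork:
    def test_threshold_one_empty_threshold_zero_complete(self):
        rng = np.random.default_rng(0)
        data = _table({f"sp{i}": rng.lognormal(size=25) * 10 for i in range(4)})
        abund = pf.AbundanceTable(data)
        m = pf.pairwise_mic(abund)
        g_empty = pf.build_network(m, data, set(data.index), NetworkConfig(edge_threshold=1.0))
        assert g_empty.number_of_edges() == 0
        g_full = pf.build_network(m, data, set(data.index), NetworkConfig(edge_threshold=0.0))
        assert g_full.number_of_edges() == 4 * 3 // 2

    def test_edge_set_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        data = _table({f"sp{i}": rng.lognormal(size=30) * 10 for i in range(5)})
        m = pf.pairwise_mic(pf.AbundanceTable(data))
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            g = pf.build_network(m, data, set(data.index), NetworkConfig(edge_threshold=thr))
            edges = set(map(frozenset, g.edges()))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_block_structure_recovered(self):
        # two correlated cliques, independence between them
        rng = np.random.default_rng(2)
        n = 200
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        data = _table(
            {
                "a1": z1,
                "a2": z1 + rng.normal(0, 0.05, n),
                "a3": np.exp(z1) + rng.normal(0, 0.05, n),
                "b1": z2,
                "b2": z2 + rng.normal(0, 0.05, n),
                "b3": z2**3 + rng.normal(0, 0.05, n),
            }
        )
        m = pf.pairwise_mic(pf.AbundanceTable(data + 100.0))  # shift: raw units
        g = pf.build_network(m, data, set(), NetworkConfig(edge_threshold=0.5))
        got = set(map(frozenset, g.edges()))
        planted = {
            frozenset(e)
            for e in [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                      ("b1", "b2"), ("b1", "b3"), ("b2", "b3")]
        }
        assert got == planted

    def test_edge_signs_and_classes(self):
        n = 40
        x = np.linspace(0.1, 4.0, n)
        noise = np.random.default_rng(3).normal(0, 0.01, n)
        data = pd.DataFrame(
            [x, x + noise, -x + noise, x * 0.5],
            index=["taxon A", "taxon B", "factor down", "factor up"],
            columns=[f"S{i}" for i in range(n)],
        )
        m = pf.pairwise_mic(pf.AbundanceTable(data.iloc[:2] * 10),
                            pf.EnvironmentTable(data.iloc[2:]))
        g = pf.build_network(m, data, {"taxon A", "taxon B"}, NetworkConfig(edge_threshold=0.9))
        assert g.edges["taxon A", "taxon B"]["sign"] == 1
        assert g.edges["taxon A", "taxon B"]["kind"] == "methanogen"
        assert g.edges["taxon A", "factor down"]["sign"] == -1
        assert g.edges["taxon A", "factor down"]["kind"] == "environment"
        assert g.edges["taxon A", "factor up"]["sign"] == 1

    def test_pearson_sign_option(self):
        n = 30
        x = np.linspace(0, 1, n)
        data = pd.DataFrame([x, -x], index=["u", "v"], columns=[f"S{i}" for i in range(n)])
        m = pd.DataFrame(np.ones((2, 2)), index=["u", "v"], columns=["u", "v"])
        g = pf.build_network(m, data, set(), NetworkConfig(sign_method="pearson"))
        assert g.edges["u", "v"]["sign"] == -1


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        topo = pf.topology(g)
        assert topo.density == pytest.approx(1.0)
        assert topo.mean_clustering == pytest.approx(1.0)
        assert topo.n_edges == 3

    def test_star(self):
        g = nx.star_graph(3)  # center 0 plus 3 leaves
        topo = pf.topology(g)
        assert topo.degrees[0] == 3
        assert topo.mean_clustering == pytest.approx(0.0)
        assert topo.density == pytest.approx(2 * 3 / (4 * 3))

    def test_empty_network_zeros(self):
        topo = pf.topology(nx.Graph())
        assert topo.n_nodes == 0 and topo.n_edges == 0
        assert topo.density == 0.0 and topo.mean_clustering == 0.0

    def test_random_graph_against_adjacency_oracle(self):
        g = nx.gnp_random_graph(12, 0.35, seed=4)
        topo = pf.topology(g)
        a = nx.to_numpy_array(g)
        n = a.shape[0]
        assert topo.density == pytest.approx(a.sum() / (n * (n - 1)))
        # local clustering from the adjacency matrix
        tri = np.diag(a @ a @ a) / 2.0
        deg = a.sum(axis=1)
        denom = deg * (deg - 1) / 2.0
        local = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
        assert topo.mean_clustering == pytest.approx(local.mean(), abs=1e-12)
        for i in range(n):
            assert topo.degrees[i] == int(deg[i])


class TestWriters:
    def test_edgelist_and_graphml_round_trip(self, tmp_path):
        abund, env, _ = pf.simulate_abundance_table(
            n_taxa=4,
            n_samples=32,
            planted_edges=[("Methanosarcina sp. 795", "Methanosarcina sp. 1H1")],
            n_factors=2,
            seed=5,
        )
        _, g = pf.cooccurrence_network(abund, env, NetworkConfig(edge_threshold=0.5))
        assert g.number_of_edges() >= 1
        edge_path = tmp_path / "edges.tsv"
        pf.network.write_edgelist_tsv(g, str(edge_path))
        back = pd.read_csv(edge_path, sep="\t")
        assert list(back.columns) == ["u", "v", "mic", "sign", "kind"]
        assert len(back) == g.number_of_edges()
        gml_path = tmp_path / "net.graphml"
        pf.network.write_graphml(g, str(gml_path))
        g2 = nx.read_graphml(gml_path)
        assert set(map(frozenset, g2.edges())) == set(map(frozenset, g.edges()))


class TestTableValidation:
    def test_negative_abundance_rejected(self):
        df = pd.DataFrame([[0.5, -0.1]], index=["t"], columns=["a", "b"])
        with pytest.raises(ValueError):
            pf.AbundanceTable(df)

    def test_fractional_closure_enforced(self):
        df = pd.DataFrame([[0.7], [0.6]], index=["t1", "t2"], columns=["a"])
        with pytest.raises(ValueError, match="sum above 1"):
            pf.AbundanceTable(df)

    def test_overlapping_labels_rejected(self):
        abund, env, _ = pf.simulate_abundance_table(n_taxa=2, n_samples=12, seed=6)
        clash = env.data.copy()
        clash.index = [abund.taxa[0]] + list(env.factors[1:])
        with pytest.raises(ValueError, match="share labels"):
            pf.pairwise_mic(abund, pf.EnvironmentTable(clash))
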