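"""Thresholded co-expression networks: correlations, edges, hubs, components."""

import numpy as np
import pandas as pd
import pytest

import icpscreen as ic
from conftest import make_sample_table


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx = x - x.mean()
    sy = y - y.mean()
    return float((sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum()))


class TestPearson:
    def test_self_and_negated(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert ic.pearson_cc(x, x) == 1.0
        assert ic.pearson_cc(x, -x + 10) == -1.0  # shifted to stay meaningful

    def test_four_point_example(self):
        assert ic.pearson_cc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_constant_vector_flagged_missing(self):
        assert np.isnan(ic.pearson_cc([1, 1, 1], [1, 2, 3]))
        assert np.isnan(ic.pearson_cc([1, 2, 3], [5, 5, 5]))

    def test_errors(self):
        with pytest.raises(ic.ValidationError, match="length mismatch"):
            ic.pearson_cc([1, 2, 3], [1, 2])
        with pytest.raises(ic.ValidationError, match="at least 3"):
            ic.pearson_cc([1, 2], [3, 4])

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert ic.pearson_cc(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)


def _net_from(values: dict, seeds, tau=0.8, **kw):
    n = len(next(iter(values.values())))
    cols = [f"T{i + 1}" for i in range(n)]
    m = ic.ExpressionMatrix(pd.DataFrame(values, index=cols).T)
    return ic.build_network(m, cols, seeds, tau=tau,
                            universe_min_fpkm=kw.pop("universe_min_fpkm", 0.0),
                            log_scale=kw.pop("log_scale", False), **kw)


def _correlated_with(base, rho, rng):
    """Vector with exact sample correlation rho to `base`, shifted positive."""
    z = (base - base.mean()) / base.std()
    e = rng.normal(size=base.size)
    e = e - e.mean()
    e = e - z * (z @ e) / (z @ z)  # orthogonalize
    v = rho * z + np.sqrt(1 - rho ** 2) * e / np.sqrt((e ** 2).mean())
    return v - v.min() + 1.0


class TestBuildNetwork:
    def test_only_strong_seed_edges_retained(self, rng):
        s = rng.normal(size=40) + 10
        a = _correlated_with(s, 0.9, rng)
        b = _correlated_with(s, 0.5, rng)
        net = _net_from({"S": s, "A": a, "B": b, "C": rng.uniform(1, 2, 40)},
                        seeds=["S"], tau=0.8)
        assert net.edges() == [("A", "S", pytest.approx(0.9, abs=1e-9))]
        assert net.nodes == {"S", "A"}

    def test_high_tau_leaves_seed_singletons(self, rng):
        vals = {f"G{i}": rng.uniform(1, 100, 30) for i in range(10)}
        net = _net_from(vals, seeds=["G0", "G1"], tau=0.999)
        assert net.n_edges == 0
        assert net.nodes == {"G0", "G1"}

    def test_universe_floor_excludes_low_genes(self, rng):
        base = rng.normal(size=20) + 50
        low = _correlated_with(base, 0.95, rng) * 0.001  # mean far below floor
        net = _net_from({"S": base, "L": low}, seeds=["S"], tau=0.5,
                        universe_min_fpkm=1.0)
        assert "L" not in net.universe and "L" not in net.nodes

    def test_all_seeds_below_floor_warns_empty(self, rng):
        vals = {"S": np.full(10, 0.01), "G": rng.uniform(5, 10, 10)}
        with pytest.warns(UserWarning, match="below the universe floor"):
            net = _net_from(vals, seeds=["S"], universe_min_fpkm=1.0)
        assert net.n_edges == 0

    def test_edge_set_invariant_under_reordering(self, small_cohort):
        m, s, a = small_cohort.matrix, small_cohort.samples, small_cohort.annotation
        seeds = [a.marker_gene] + a.icp_genes
        net1 = ic.build_network(m, s.tumor_samples, seeds, condition="t")
        perm_genes = list(reversed(m.gene_ids))
        perm_samples = list(reversed(s.tumor_samples))
        m2 = m.subset(genes=perm_genes)
        net2 = ic.build_network(m2, perm_samples, seeds, condition="t")
        e1 = [(u, v) for u, v, _ in net1.edges()]
        e2 = [(u, v) for u, v, _ in net2.edges()]
        assert e1 == e2
        np.testing.assert_allclose([c for *_, c in net1.edges()],
                                   [c for *_, c in net2.edges()], atol=1e-12)

    def test_raising_tau_never_adds_edges(self, small_cohort):
        m, s, a = small_cohort.matrix, small_cohort.samples, small_cohort.annotation
        seeds = [a.marker_gene] + a.icp_genes
        lo = ic.build_network(m, s.tumor_samples, seeds, tau=0.6, condition="t")
        hi = ic.build_network(m, s.tumor_samples, seeds, tau=0.85, condition="t")
        lo_edges = {(u, v) for u, v, _ in lo.edges()}
        hi_edges = {(u, v) for u, v, _ in hi.edges()}
        assert hi_edges <= lo_edges

    def test_missing_seed_rejected(self, small_cohort):
        m, s = small_cohort.matrix, small_cohort.samples
        with pytest.raises(ic.ValidationError, match="NOPE"):
            ic.build_network(m, s.tumor_samples, ["NOPE"], condition="t")


class TestComponentsAndHubs:
    def _manual_net(self, edges, extra_nodes=()):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for u, v in edges:
            g.add_edge(u, v, cc=0.9)
        return ic.CoexpressionNetwork("toy", g, frozenset(extra_nodes) or
                                      frozenset(g.nodes), frozenset(g.nodes), 0.8)

    def test_isolated_seeds_are_singletons(self):
        net = self._manual_net([], extra_nodes=["A", "B", "C"])
        assert ic.connected_components(net) == [{"A"}, {"B"}, {"C"}]

    def test_path_plus_isolate(self):
        net = self._manual_net([("A", "B"), ("B", "C")], extra_nodes=["D"])
        comps = ic.connected_components(net)
        assert comps == [{"A", "B", "C"}, {"D"}]
        assert sum(len(c) for c in comps) == len(net.nodes)

    def test_star_hub_called_strictly(self):
        net = self._manual_net([("HUB", f"L{i}") for i in range(5)])
        assert ic.hub_genes(net, 4) == {"HUB"}
        assert ic.hub_genes(net, 5) == set()  # strict: degree must exceed

    def test_empty_network_no_hubs(self):
        net = self._manual_net([], extra_nodes=["A"])
        assert ic.hub_genes(net, 0) == set()


class TestMarkerCorrelations:
    def test_marker_in_panel_and_bounds(self, small_cohort):
        m, s, a = small_cohort.matrix, small_cohort.samples, small_cohort.annotation
        panel = [a.marker_gene] + a.icp_genes
        tab = ic.marker_correlations(m, s.tumor_samples, a.marker_gene, panel)
        assert len(tab) == len(panel)
        assert tab.iloc[0]["gene"] == a.marker_gene
        assert tab.iloc[0]["cc"] == 1.0
        finite = tab["cc"].dropna()
        assert ((finite >= -1) & (finite <= 1)).all()
        assert (finite.diff().dropna() <= 1e-12).all()  # sorted descending

    def test_noise_free_module_panel_perfect(self):
        c = ic.simulate_cohort(ic.SimParams(n_pairs=10, n_module=9, n_null=5,
                                            sigma=0.0, rng_seed=33))
        panel = sorted(c.truth.module_genes)
        tab = ic.marker_correlations(c.matrix, c.samples.tumor_samples,
                                     c.truth.marker_gene, panel)
        np.testing.assert_allclose(tab["cc"], 1.0, atol=1e-9)
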