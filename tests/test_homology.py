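import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evonet.homology import (
    FilterConfig,
    cluster_network_genes,
    collapse_clusters,
    domain_filter_detailed,
    domain_filter_simple,
    filter_hits,
    rank_domains,
)
from evonet.netstats import GeneNetwork
from tests.conftest import make_datastore


def random_hits(rng: np.random.Generator, n: int, genes: list[str]) -> pd.DataFrame:
    rows = []
    for _ in range(n):
        a, b = rng.choice(genes, size=2, replace=False)
        rows.append((a, b, float(rng.uniform(0, 1000)), float(rng.uniform(0, 1))))
    return pd.DataFrame(rows, columns=["query_gene", "subject_gene", "sw_score", "identity"])


class TestFilterHits:
    def test_boundary_hit_retained_inclusively(self):
        hits = pd.DataFrame(
            [("a", "b", 500.0, 0.5)],
            columns=["query_gene", "subject_gene", "sw_score", "identity"],
        )
        cfg = FilterConfig(sw_min=500, identity_min=0.5)
        assert len(filter_hits(hits, cfg)) == 1

    def test_below_score_threshold_removed(self):
        hits = pd.DataFrame(
            [("a", "b", 499.0, 0.9)],
            columns=["query_gene", "subject_gene", "sw_score", "identity"],
        )
        assert len(filter_hits(hits, FilterConfig(sw_min=500, identity_min=0.0))) == 0

    def test_matches_row_by_row_scan_and_preserves_order(self, rng):
        genes = [f"g{i}" for i in range(30)]
        hits = random_hits(rng, 200, genes)
        cfg = FilterConfig(sw_min=400, identity_min=0.3)
        got = filter_hits(hits, cfg)
        expected_idx = [
            i for i, row in hits.iterrows()
            if row["sw_score"] >= 400 and row["identity"] >= 0.3
        ]
        assert list(got.index) == expected_idx

    @given(
        sw1=st.floats(0, 1000), sw2=st.floats(0, 1000),
        id1=st.floats(0, 1), id2=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_is_monotone(self, sw1, sw2, id1, id2):
        rng = np.random.default_rng(5)
        hits = random_hits(rng, 80, [f"g{i}" for i in range(10)])
        lo = FilterConfig(sw_min=min(sw1, sw2), identity_min=min(id1, id2))
        hi = FilterConfig(sw_min=max(sw1, sw2), identity_min=max(id1, id2))
        kept_lo = set(filter_hits(hits, lo).index)
        kept_hi = set(filter_hits(hits, hi).index)
        assert kept_hi <= kept_lo


class TestRankDomains:
    def test_ordered_by_descending_count(self):
        domains = pd.DataFrame(
            [("g1", "D1"), ("g2", "D1"), ("g3", "D1"),
             ("g1", "D2"), ("g2", "D2"), ("g1", "D3")],
            columns=["gene_id", "domain_id"],
        )
        assert rank_domains({"g1", "g2", "g3"}, domains) == ["D1", "D2", "D3"]

    def test_ties_broken_lexicographically(self):
        domains = pd.DataFrame(
            [("g1", "Db"), ("g2", "Db"), ("g1", "Da"), ("g2", "Da")],
            columns=["gene_id", "domain_id"],
        )
        assert rank_domains({"g1", "g2"}, domains) == ["Da", "Db"]

    def test_matches_count_then_sort_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        doms = [f"D{i}" for i in range(8)]
        rows = {(rng.choice(genes), rng.choice(doms)) for _ in range(60)}
        domains = pd.DataFrame(sorted(rows), columns=["gene_id", "domain_id"])
        candidates = set(rng.choice(genes, size=12, replace=False))
        counts = {
            d: sum(
                1 for g in candidates
                if ((domains["gene_id"] == g) & (domains["domain_id"] == d)).any()
            )
            for d in doms
        }
        expected = sorted(
            (d for d in doms if counts[d] > 0), key=lambda d: (-counts[d], d)
        )
        assert rank_domains(candidates, domains) == expected


class TestDomainFilters:
    def test_simple_T0_keeps_all(self):
        gd = {"g1": frozenset(), "g2": frozenset({"D1"})}
        assert domain_filter_simple({"g1", "g2"}, gd, ["D1"], 0) == {"g1", "g2"}

    def test_simple_missing_required_domain_removed(self):
        gd = {"g1": frozenset({"D1"}), "g2": frozenset({"D1", "D2"})}
        assert domain_filter_simple({"g1", "g2"}, gd, ["D1", "D2"], 2) == {"g2"}

    def test_simple_T_beyond_ranking_requires_whole_ranking(self):
        gd = {"g1": frozenset({"D1", "D2"}), "g2": frozenset({"D1"})}
        assert domain_filter_simple({"g1", "g2"}, gd, ["D1", "D2"], 99) == {"g1"}

    def test_detailed_keeps_genes_with_any_required_domain(self):
        gd = {"g1": frozenset({"D5", "D9"}), "g2": frozenset()}
        assert domain_filter_detailed({"g1", "g2"}, gd, {"D5"}) == {"g1"}

    def test_detailed_empty_requirement_keeps_all(self):
        gd = {"g1": frozenset(), "g2": frozenset({"D1"})}
        assert domain_filter_detailed({"g1", "g2"}, gd, set()) == {"g1", "g2"}

    def test_random_instances_match_brute_force(self, rng):
        genes = [f"g{i}" for i in range(25)]
        doms = [f"D{i}" for i in range(6)]
        for _ in range(20):
            gd = {
                g: frozenset(rng.choice(doms, size=int(rng.integers(0, 5)), replace=False))
                for g in genes
            }
            ranking = list(rng.permutation(doms))
            T = int(rng.integers(0, 8))
            got = domain_filter_simple(genes, gd, ranking, T)
            assert got == {g for g in genes if set(ranking[:T]) <= gd[g]}
            required = set(rng.choice(doms, size=int(rng.integers(0, 4)), replace=False))
            got = domain_filter_detailed(genes, gd, required)
            expect = {g for g in genes if not required or required & gd[g]}
            assert got == expect


def _network_of(genes: list[str]) -> GeneNetwork:
    net = GeneNetwork()
    for g in genes:
        net.add_node(f"n_{g}", "gene", gene_id=g)
    return net


def _union_find_components(genes, edges):
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for g in genes:
        comps.setdefault(find(g), set()).add(g)
    return {frozenset(c) for c in comps.values()}


class TestClustering:
    def _datastore(self, genes, hits):
        orgs = pd.DataFrame(
            [("ref", "ref", ("Cellular Organisms", "X", "Ref"))],
            columns=["org_code", "name", "lineage"],
        )
        return make_datastore(orgs, [(g, "ref") for g in genes], hits)

    def test_no_qualifying_hits_gives_singletons(self):
        genes = ["a", "b", "c"]
        ds = self._datastore(genes, [("a", "b", 10.0, 0.1)])
        net = _network_of(genes)
        asn = cluster_network_genes(net, ds, FilterConfig(sw_min=500, identity_min=0.5))
        assert {frozenset(c) for c in asn.clusters} == {
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"})
        }

    def test_transitive_hits_form_one_cluster(self):
        genes = ["a", "b", "c"]
        ds = self._datastore(genes, [("a", "b", 900.0, 0.9), ("b", "c", 900.0, 0.9)])
        net = _network_of(genes)
        asn = cluster_network_genes(net, ds, FilterConfig())
        assert {frozenset(c) for c in asn.clusters} == {frozenset({"a", "b", "c"})}

    def test_unresolvable_gene_node_raises_with_name(self):
        ds = self._datastore(["a"], [])
        net = _network_of(["a", "ghost"])
        with pytest.raises(KeyError, match="ghost"):
            cluster_network_genes(net, ds, FilterConfig())

    def test_matches_union_find_oracle_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(15)]
        for _ in range(15):
            hits = random_hits(rng, 25, genes)
            ds = self._datastore(genes, list(hits.itertuples(index=False, name=None)))
            cfg = FilterConfig(sw_min=300, identity_min=0.4)
            asn = cluster_network_genes(_network_of(genes), ds, cfg)
            kept = filter_hits(ds.hits, cfg)
            edges = list(kept[["query_gene", "subject_gene"]].itertuples(index=False, name=None))
            assert set(asn.clusters) == _union_find_components(genes, edges)

    def test_lowering_thresholds_never_increases_cluster_count(self, rng):
        genes = [f"g{i}" for i in range(12)]
        hits = random_hits(rng, 30, genes)
        ds = self._datastore(genes, list(hits.itertuples(index=False, name=None)))
        counts = []
        for id_min in [0.9, 0.6, 0.3, 0.0]:
            asn = cluster_network_genes(
                _network_of(genes), ds, FilterConfig(sw_min=0, identity_min=id_min)
            )
            counts.append(len(asn.clusters))
        assert counts == sorted(counts, reverse=True)


class TestCollapseClusters:
    def _cluster(self, net, ds, cfg=FilterConfig()):
        return cluster_network_genes(net, ds, cfg)

    def test_all_singletons_is_isomorphic_to_input(self):
        genes = ["a", "b", "c"]
        orgs = pd.DataFrame(
            [("ref", "ref", ("Cellular Organisms", "X", "Ref"))],
            columns=["org_code", "name", "lineage"],
        )
        ds = make_datastore(orgs, [(g, "ref") for g in genes])
        net = _network_of(genes)
        net.add_edge("n_a", "n_b")
        asn = self._cluster(net, ds)
        out = collapse_clusters(net, asn)
        assert out.graph.number_of_nodes() == 3
        assert out.graph.number_of_edges() == 1

    def test_triangle_with_two_gene_cluster_collapses_to_edge(self):
        genes = ["a", "b", "c"]
        orgs = pd.DataFrame(
            [("ref", "ref", ("Cellular Organisms", "X", "Ref"))],
            columns=["org_code", "name", "lineage"],
        )
        ds = make_datastore(orgs, [(g, "ref") for g in genes],
                            [("a", "b", 900.0, 0.9)])
        net = _network_of(genes)
        net.add_edge("n_a", "n_b")
        net.add_edge("n_b", "n_c")
        net.add_edge("n_a", "n_c")
        out = collapse_clusters(net, self._cluster(net, ds))
        assert out.graph.number_of_nodes() == 2
        assert out.graph.number_of_edges() == 1  # duplicates merged, self-loop dropped

    def test_node_count_is_cluster_count_plus_non_gene_nodes(self, rng):
        genes = [f"g{i}" for i in range(10)]
        orgs = pd.DataFrame(
            [("ref", "ref", ("Cellular Organisms", "X", "Ref"))],
            columns=["org_code", "name", "lineage"],
        )
        hits = random_hits(rng, 12, genes)
        ds = make_datastore(orgs, [(g, "ref") for g in genes],
                            list(hits.itertuples(index=False, name=None)))
        net = _network_of(genes)
        net.add_node("cpd1", "compound")
        net.add_node("map1", "map")
        net.add_edge("cpd1", "n_g0")
        asn = self._cluster(net, ds, FilterConfig(sw_min=200, identity_min=0.2))
        out = collapse_clusters(net, asn)
        assert out.graph.number_of_nodes() == len(asn.clusters) + 2

    def test_reachability_between_connected_clusters_preserved(self, rng):
        import networkx as nx

        genes = [f"g{i}" for i in range(10)]
        orgs = pd.DataFrame(
            [("ref", "ref", ("Cellular Organisms", "X", "Ref"))],
            columns=["org_code", "name", "lineage"],
        )
        hits = random_hits(rng, 10, genes)
        ds = make_datastore(orgs, [(g, "ref") for g in genes],
                            list(hits.itertuples(index=False, name=None)))
        net = _network_of(genes)
        for _ in range(12):
            a, b = rng.choice(genes, size=2, replace=False)
            net.add_edge(f"n_{a}", f"n_{b}")
        asn = self._cluster(net, ds, FilterConfig(sw_min=200, identity_min=0.2))
        out = collapse_clusters(net, asn)
        label_of = {g: f"cluster:{asn.labels[g]}" for g in genes}
        for a in genes:
            for b in genes:
                connected_in = nx.has_path(net.graph, f"n_{a}", f"n_{b}")
                if connected_in and label_of[a] != label_of[b]:
                    assert nx.has_path(out.graph, label_of[a], label_of[b])
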