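"""CorSP scoring, threshold selection, agglomeration and extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from corsp.corsp_core import (AUTO, CorsPair, NodeOfInterest, Subpathway,
                              SubpathwayConfig, cluster_interest_nodes,
                              corsp_score, extract_subpathways,
                              identify_subpathways, map_interest_to_nodes,
                              mean_region_pcc, node_pair_pcc,
                              select_threshold_m)
from corsp.interest_screen import InterestSet
from corsp.kgml_graph import (Entry, Reaction, UNREACHABLE,
                              reconstruct_graph, shortest_path_lengths)

from conftest import chain_definition, make_definition


@pytest.fixture
def chain_graph():
    # C1 - K1 - C2 - K2 - C3 - K3 - C4
    return reconstruct_graph(chain_definition(4))


def _noi(node_id, node_type="compound", mols=("m1",), pathway="path:00001"):
    return NodeOfInterest(pathway_id=pathway, node_id=node_id,
                          node_type=node_type, mapped_molecules=tuple(mols))


class TestMapInterest:
    def test_direct_compound_match(self, chain_graph):
        interest = InterestSet(metabolites={"C00001"}, genes=set())
        nodes = map_interest_to_nodes(chain_graph, interest, {})
        assert [n.node_id for n in nodes] == ["C00001"]
        assert nodes[0].mapped_molecules == ("C00001",)

    def test_gene_joins_via_ko(self, chain_graph):
        interest = InterestSet(metabolites=set(), genes={"g1"})
        nodes = map_interest_to_nodes(chain_graph, interest,
                                      {"g1": "K00001"})
        assert [n.node_id for n in nodes] == ["K00001"]
        assert nodes[0].mapped_molecules == ("g1",)

    def test_multi_ko_enzyme_node(self):
        defn = make_definition(entries=[
            Entry("c1", "compound", ("C00001",)),
            Entry("e1", "enzyme", ("K00001", "K00002")),
        ], reactions=[Reaction(("c1",), (), ("e1",))])
        g = reconstruct_graph(defn)
        interest = InterestSet(metabolites=set(), genes={"g1"})
        nodes = map_interest_to_nodes(g, interest, {"g1": "K00001"})
        assert len(nodes) == 1
        assert nodes[0].mapped_molecules == ("g1",)

    def test_empty_interest_set(self, chain_graph):
        assert map_interest_to_nodes(chain_graph, InterestSet(), {}) == []

    def test_unannotated_gene_is_unmappable(self, chain_graph):
        interest = InterestSet(metabolites=set(), genes={"orphan"})
        assert map_interest_to_nodes(chain_graph, interest, {}) == []


class TestNodePairPcc:
    def _profiles(self):
        samples = [f"S{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        rows = {
            "m1": base,
            "m1copy": base.copy(),
            "g1": rng.normal(size=10),
            "g2": rng.normal(size=10),
        }
        return pd.DataFrame(rows, index=samples).T

    def test_identical_single_molecule_profiles(self):
        profiles = self._profiles()
        c = node_pair_pcc(_noi("a", mols=("m1",)), _noi("b", mols=("m1copy",)),
                          profiles)
        assert c == pytest.approx(1.0)

    def test_max_abs_aggregation(self):
        samples = [f"S{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        m1 = rng.normal(size=20)
        # construct g1 weakly and g2 strongly negatively correlated with m1
        g1 = 0.2 * m1 + np.sqrt(1 - 0.04) * rng.normal(size=20)
        g2 = -m1
        profiles = pd.DataFrame([m1, g1, g2], index=["m1", "g1", "g2"],
                                columns=samples)
        c = node_pair_pcc(_noi("a", "enzyme", ("g1", "g2")),
                          _noi("b", "compound", ("m1",)), profiles,
                          aggregation="max_abs")
        assert c == pytest.approx(-1.0)

    def test_mean_aggregation_enumerated(self):
        samples = [f"S{i}" for i in range(4)]
        m1 = np.array([1.0, 2.0, 3.0, 4.0])
        g1 = np.array([1.0, 2.0, 3.0, 5.0])
        g2 = -m1
        profiles = pd.DataFrame([m1, g1, g2], index=["m1", "g1", "g2"],
                                columns=samples)
        from corsp.interest_screen import pearson_corr
        expected = np.mean([pearson_corr(g1, m1, min_periods=3),
                            pearson_corr(g2, m1, min_periods=3)])
        c = node_pair_pcc(_noi("a", "enzyme", ("g1", "g2")),
                          _noi("b", "compound", ("m1",)), profiles,
                          aggregation="mean", min_periods=3)
        assert c == pytest.approx(expected)

    def test_degenerate_pair_is_nan(self):
        samples = [f"S{i}" for i in range(6)]
        profiles = pd.DataFrame([[1.0] * 6, [1, 2, 3, 4, 5, 6]],
                                index=["m1", "m2"], columns=samples)
        c = node_pair_pcc(_noi("a", mols=("m1",)), _noi("b", mols=("m2",)),
                          profiles)
        assert np.isnan(c)


class TestCorspScore:
    def test_forced_values(self):
        assert corsp_score(1.0, 1, beta=10.0) == pytest.approx(10.0)
        assert corsp_score(0.0, 3, beta=10.0) == 0.0

    def test_unreachable_is_nan(self):
        assert np.isnan(corsp_score(0.9, UNREACHABLE))

    def test_strict_monotonicity_grid(self):
        eps = 1e-6
        for c in np.arange(0.1, 1.0, 0.1):
            for d in range(1, 7):
                assert corsp_score(c + eps, d) > corsp_score(c, d)
                assert corsp_score(c, d + 1) < corsp_score(c, d)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            corsp_score(0.5, 0)


def threshold_oracle(scores, pass_fraction):
    """Enumerate candidate thresholds among observed values."""
    n = len(scores)
    best = None
    for v in sorted(set(scores)):
        if sum(s > v for s in scores) / n >= pass_fraction:
            best = v if best is None else max(best, v)
    if best is None:
        return float(np.nextafter(min(scores), -np.inf))
    return float(best)


class TestSelectThresholdM:
    def test_enumerated_example(self):
        m = select_threshold_m(range(1, 11), pass_fraction=0.70)
        assert m == 3  # exactly 7 of 10 scores strictly greater

    def test_all_equal_degenerate(self):
        m = select_threshold_m([5.0] * 8, pass_fraction=0.70)
        assert m == np.nextafter(5.0, -np.inf)
        assert np.mean(np.array([5.0] * 8) > m) == 1.0

    def test_near_total_pass_fraction(self):
        scores = [2.0, 3.0, 4.0]
        m = select_threshold_m(scores, pass_fraction=0.999)
        assert m < 2.0
        assert all(s > m for s in scores)

    def test_matches_enumeration_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            scores = list(np.round(rng.normal(size=rng.integers(1, 40)), 2))
            pf = float(rng.uniform(0.05, 0.95))
            assert select_threshold_m(scores, pf) == \
                pytest.approx(threshold_oracle(scores, pf))

    def test_empty_scores_error(self):
        with pytest.raises(ValueError):
            select_threshold_m([], 0.7)


def _pair(i, j, score):
    return CorsPair(node_i=i, node_j=j, c_ij=0.9, d_ij=2, score=score,
                    beta=10.0)


class TestClustering:
    def test_no_pair_passes_singletons(self, chain_graph):
        pairs = [_pair("C00001", "C00003", 1.0)]
        sets = cluster_interest_nodes(chain_graph, pairs, m=5.0)
        assert sorted(sets, key=min) == [{"C00001"}, {"C00003"}]

    def test_chain_merge_with_path_injection(self, chain_graph):
        pairs = [_pair("C00001", "C00002", 9.0),
                 _pair("C00002", "C00003", 9.0)]
        sets = cluster_interest_nodes(chain_graph, pairs, m=5.0)
        assert sets == [{"C00001", "K00001", "C00002", "K00002", "C00003"}]

    def test_fixpoint_invariant_to_pair_order(self, chain_graph):
        pairs = [_pair("C00001", "C00002", 9.0),
                 _pair("C00002", "C00003", 9.0),
                 _pair("C00001", "C00004", 2.0),
                 _pair("C00003", "C00004", 7.0)]
        rng = np.random.default_rng(2)
        reference = cluster_interest_nodes(chain_graph, pairs, m=5.0)
        for _ in range(20):
            shuffled = list(pairs)
            rng.shuffle(shuffled)
            assert cluster_interest_nodes(chain_graph, shuffled, m=5.0) == \
                reference

    def test_raising_m_never_enlarges_sets(self, chain_graph):
        pairs = [_pair("C00001", "C00002", 9.0),
                 _pair("C00002", "C00003", 6.0),
                 _pair("C00003", "C00004", 3.0)]
        prev = None
        for m in [0.0, 2.0, 5.0, 8.0, 10.0]:
            sets = cluster_interest_nodes(chain_graph, pairs, m)
            if prev is not None:
                for s in sets:
                    assert any(s <= p for p in prev)
            prev = sets


class TestExtractSubpathways:
    def test_size_filter(self, chain_graph):
        sets = [{"C00001", "K00001", "C00002", "K00002"},  # 4 nodes: dropped
                {"C00001", "K00001", "C00002", "K00002", "C00003"}]
        subs = extract_subpathways(chain_graph, sets, s=5)
        assert len(subs) == 1
        assert len(subs[0].node_ids) == 5

    def test_empty_input(self, chain_graph):
        assert extract_subpathways(chain_graph, [], s=5) == []

    def test_id_ordering_by_size_then_anchor(self):
        g = reconstruct_graph(chain_definition(8, pathway_id="path:00561"))
        big = {"C00001", "K00001", "C00002", "K00002", "C00003", "K00003",
               "C00004"}
        small = {"C00005", "K00005", "C00006", "K00006", "C00007", "K00007"}
        subs = extract_subpathways(g, [small, big], s=5)
        assert [(s.subpathway_id, len(s.node_ids)) for s in subs] == \
            [("path:00561_1", 7), ("path:00561_2", 6)]

    def test_interest_subset_recorded(self, chain_graph):
        sets = [{"C00001", "K00001", "C00002", "K00002", "C00003"}]
        subs = extract_subpathways(chain_graph, sets, s=5,
                                   interest_node_ids=["C00001", "C00003"])
        assert subs[0].interest_node_ids == frozenset({"C00001", "C00003"})


class TestMeanRegionPcc:
    def _setup(self, pcc_values):
        samples = [f"S{i}" for i in range(30)]
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        rows, names = [base], ["m1"]
        for k, target in enumerate(pcc_values):
            rows.append(target * base
                        + np.sqrt(1 - target ** 2) * rng.normal(size=30))
            names.append(f"m{k + 2}")
        return pd.DataFrame(rows, index=names, columns=samples)

    def test_single_pair(self):
        samples = [f"S{i}" for i in range(10)]
        x = np.arange(10.0)
        y = 0.9 * x + np.sqrt(1 - 0.81) * np.random.default_rng(4).normal(size=10)
        profiles = pd.DataFrame([x, y], index=["m1", "m2"], columns=samples)
        from corsp.interest_screen import pearson_corr
        expected = pearson_corr(x, y)
        sub = Subpathway("p_1", "p", frozenset({"a", "b"}),
                         frozenset({"a", "b"}))
        lookup = {"a": _noi("a", mols=("m1",)), "b": _noi("b", mols=("m2",))}
        assert mean_region_pcc(sub, lookup, profiles) == \
            pytest.approx(expected)

    def test_mean_over_three_molecules(self):
        samples = [f"S{i}" for i in range(6)]
        m1 = np.array([1.0, 2, 3, 4, 5, 6])
        m2 = 2 * m1
        m3 = m1 + np.array([0.0, 0.2, -0.1, 0.3, -0.2, 0.1])
        profiles = pd.DataFrame([m1, m2, m3], index=["m1", "m2", "m3"],
                                columns=samples)
        from corsp.interest_screen import pearson_corr
        expected = np.mean([pearson_corr(m1, m2), pearson_corr(m1, m3),
                            pearson_corr(m2, m3)])
        sub = Subpathway("p_1", "p", frozenset({"a", "b", "c"}),
                         frozenset({"a", "b", "c"}))
        lookup = {"a": _noi("a", mols=("m1",)), "b": _noi("b", mols=("m2",)),
                  "c": _noi("c", mols=("m3",))}
        assert mean_region_pcc(sub, lookup, profiles) == \
            pytest.approx(expected)

    def test_single_molecule_sentinel(self):
        profiles = self._setup([])
        sub = Subpathway("p_1", "p", frozenset({"a"}), frozenset({"a"}))
        lookup = {"a": _noi("a", mols=("m1",))}
        assert mean_region_pcc(sub, lookup, profiles) is None


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(pass_fraction=0.0), dict(pass_fraction=1.0),
        dict(s=0), dict(beta=0.0), dict(beta=-1.0),
    ])
    def test_rejects_illegal_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SubpathwayConfig(**kwargs)


class TestIdentifySubpathways:
    def test_planted_region_recovered(self, planted_dataset):
        d = planted_dataset
        region = d["truth"].regions[0]
        interest = InterestSet(
            metabolites={m for m in region["molecules"] if m.startswith("C")},
            genes={m for m in region["molecules"] if m.startswith("g")})
        profiles = pd.concat([d["metab"], d["gene"]])
        res = identify_subpathways(d["graphs"], interest, profiles,
                                   d["gene_to_ko"])
        assert len(res.subpathways) >= 1
        best = max(res.subpathways,
                   key=lambda s: len(s.node_ids & set(region["node_ids"])))
        from corsp.synthetic_data import node_jaccard
        assert node_jaccard(best.node_ids, set(region["node_ids"])) >= 0.8

    def test_connectivity_of_all_regions(self, planted_dataset):
        import networkx as nx
        d = planted_dataset
        region = d["truth"].regions[0]
        interest = InterestSet(
            metabolites={m for m in region["molecules"] if m.startswith("C")},
            genes={m for m in region["molecules"] if m.startswith("g")})
        profiles = pd.concat([d["metab"], d["gene"]])
        res = identify_subpathways(d["graphs"], interest, profiles,
                                   d["gene_to_ko"])
        graph_by_id = {g.pathway_id: g for g in d["graphs"]}
        for sub in res.subpathways:
            g = graph_by_id[sub.pathway_id]
            assert nx.is_connected(g.graph.subgraph(sub.node_ids))
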