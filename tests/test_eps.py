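"""EPS neighborhood scoring, ranking, nomination and concordance."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosphoresponse.core import DrugInfo, PerturbationProfile
from phosphoresponse.eps import (
    ConcordanceResult,
    InteractionNetwork,
    UnmappedAnalyteError,
    compute_eps_table,
    eps_score,
    nominate_combinations,
    rank_tractable,
    read_network,
    topk_concordance,
    write_network,
)


def star_network():
    """Star: center A with leaves B, C; one analyte per node."""
    g = nx.Graph([("A", "B"), ("A", "C")])
    return InteractionNetwork(
        graph=g,
        tractable={n: True for n in g.nodes},
        analyte_map={"A_P1": "A", "B_P1": "B", "C_P1": "C"},
    )


def brute_force_eps(profile, network):
    """Independent oracle: triple loop over (node, neighbor, analyte)."""
    out = {}
    for node in network.graph.nodes:
        total = 0.0
        for neighbor in network.graph.nodes:
            if not network.graph.has_edge(node, neighbor):
                continue
            for analyte, mapped in network.analyte_map.items():
                if mapped == neighbor:
                    total += abs(profile.changes[analyte])
        out[node] = total
    return out


class TestEpsScore:
    def test_star_center_sums_leaf_changes(self):
        profile = PerturbationProfile("S", "d", {"A_P1": 0.1, "B_P1": -0.5, "C_P1": 0.3})
        scores = eps_score(profile, star_network()).set_index("entity")["eps"]
        assert scores["A"] == pytest.approx(0.8)
        assert scores["B"] == pytest.approx(0.1)  # only the center is B's neighbor
        assert scores["C"] == pytest.approx(0.1)

    def test_isolated_node_scores_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("Z")
        net = InteractionNetwork(
            graph=g, tractable={}, analyte_map={"A_P1": "A", "B_P1": "B", "Z_P1": "Z"}
        )
        profile = PerturbationProfile("S", "d", {"A_P1": 1.0, "B_P1": 1.0, "Z_P1": 9.0})
        scores = eps_score(profile, net).set_index("entity")["eps"]
        assert scores["Z"] == 0.0

    def test_unmapped_analyte_listed_in_error(self):
        profile = PerturbationProfile("S", "d", {"A_P1": 0.1, "GHOST": 0.2})
        with pytest.raises(UnmappedAnalyteError, match="GHOST"):
            eps_score(profile, star_network())

    def test_multisite_entities_share_neighborhood_sum(self):
        g = nx.Graph([("AKT1", "MTOR"), ("AKT1", "GSK3B")])
        net = InteractionNetwork(
            graph=g,
            tractable={n: True for n in g.nodes},
            analyte_map={
                "AKT1_T308": "AKT1", "AKT1_S473": "AKT1",
                "MTOR_P1": "MTOR", "GSK3B_P1": "GSK3B",
            },
        )
        profile = PerturbationProfile(
            "S", "d",
            {"AKT1_T308": -1.0, "AKT1_S473": -0.5, "MTOR_P1": 0.2, "GSK3B_P1": 0.3},
        )
        scores = eps_score(profile, net).set_index("entity")["eps"]
        assert "AKT1" not in scores.index
        assert scores["AKT1_T308"] == scores["AKT1_S473"] == pytest.approx(0.5)
        # the two site analytes contribute jointly to the neighbors' EPS
        assert scores["MTOR"] == pytest.approx(1.5)

    def test_site_self_term_separates_sites(self):
        g = nx.Graph([("AKT1", "MTOR")])
        net = InteractionNetwork(
            graph=g,
            tractable={n: True for n in g.nodes},
            analyte_map={"AKT1_T308": "AKT1", "AKT1_S473": "AKT1", "MTOR_P1": "MTOR"},
        )
        profile = PerturbationProfile(
            "S", "d", {"AKT1_T308": -1.0, "AKT1_S473": -0.25, "MTOR_P1": 0.5}
        )
        scores = eps_score(profile, net, self_weight=1.0).set_index("entity")["eps"]
        assert scores["AKT1_T308"] == pytest.approx(0.5 + 1.0)
        assert scores["AKT1_S473"] == pytest.approx(0.5 + 0.25)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        g = nx.gnp_random_graph(n, 0.2, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        amap = {f"N{i}_P1": f"N{i}" for i in range(n)}
        net = InteractionNetwork(graph=g, tractable={}, analyte_map=amap)
        profile = PerturbationProfile(
            "S", "d", {a: float(v) for a, v in zip(amap, rng.normal(size=n))}
        )
        expected = brute_force_eps(profile, net)
        got = eps_score(profile, net).set_index("entity")["eps"]
        for node, value in expected.items():
            assert got[node] == pytest.approx(value, abs=1e-12)

    def test_scaling_changes_scales_eps_and_preserves_ranks(self):
        net = star_network()
        profile = PerturbationProfile("S", "d", {"A_P1": 0.1, "B_P1": -0.5, "C_P1": 0.3})
        scaled = PerturbationProfile(
            "S", "d", {k: 3.0 * v for k, v in profile.changes.items()}
        )
        s1 = eps_score(profile, net)
        s2 = eps_score(scaled, net)
        assert np.allclose(3.0 * s1["eps"], s2["eps"])
        assert rank_tractable(s1, net.tractable).equals(rank_tractable(s2, net.tractable))

    def test_removing_an_edge_never_increases_endpoint_eps(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        amap = {f"{n}_P1": n for n in g.nodes}
        profile = PerturbationProfile(
            "S", "d", {a: float(v) for a, v in zip(sorted(amap), rng.normal(size=12))}
        )
        net = InteractionNetwork(graph=g, tractable={}, analyte_map=amap)
        before = eps_score(profile, net).set_index("entity")["eps"]
        u, v = next(iter(g.edges))
        g2 = g.copy()
        g2.remove_edge(u, v)
        net2 = InteractionNetwork(graph=g2, tractable={}, analyte_map=amap)
        after = eps_score(profile, net2).set_index("entity")["eps"]
        assert after[u] <= before[u] + 1e-12
        assert after[v] <= before[v] + 1e-12


class TestRankTractable:
    def _scores(self, eps, tractable):
        df = pd.DataFrame(
            {"entity": list(eps), "node": list(eps), "eps": list(eps.values())}
        )
        return df, tractable

    def test_descending_ranks(self):
        df, tr = self._scores({"X": 3.0, "Y": 2.0, "Z": 1.0}, {n: True for n in "XYZ"})
        ranks = rank_tractable(df, tr).set_axis(df["entity"])
        assert ranks.to_dict() == {"X": 1, "Y": 2, "Z": 3}

    def test_ties_take_minimum_rank(self):
        df, tr = self._scores({"X": 2.0, "Y": 2.0, "Z": 1.0}, {n: True for n in "XYZ"})
        ranks = rank_tractable(df, tr).set_axis(df["entity"])
        assert ranks.to_dict() == {"X": 1, "Y": 1, "Z": 3}

    def test_non_tractable_excluded_but_scored(self):
        df, tr = self._scores(
            {"X": 3.0, "Y": 2.0, "Z": 1.0}, {"X": True, "Y": False, "Z": True}
        )
        ranks = rank_tractable(df, tr).set_axis(df["entity"])
        assert np.isnan(ranks["Y"])
        assert ranks["X"] == 1 and ranks["Z"] == 2

    def test_no_tractable_entity_is_an_error(self):
        df, _ = self._scores({"X": 1.0}, {"X": False})
        with pytest.raises(ValueError, match="tractable"):
            rank_tractable(df, {"X": False})


class TestNomination:
    def test_partner_on_hot_neighborhood_ranked_first(self, small_cohort):
        """Planted synergy pairs sit on top-ranked targets, so the nominated
        first partner must achieve the minimum rank among partners."""
        noms = nominate_combinations(
            small_cohort.eps_table, small_cohort.drugs, small_cohort.network, k=3
        )
        sample, anchor = noms.iloc[0][["sample", "anchor"]]
        block = noms[(noms["sample"] == sample) & (noms["anchor"] == anchor)]
        assert list(block["order"]) == sorted(block["order"])
        assert block["rank"].is_monotonic_increasing

    def test_k_larger_than_partner_count_returns_all(self, small_cohort):
        noms = nominate_combinations(
            small_cohort.eps_table, small_cohort.drugs, small_cohort.network, k=99
        )
        n_drugs = len(small_cohort.drugs)
        block = noms.groupby(["sample", "anchor"]).size()
        assert (block <= n_drugs - 1).all() and (block > 0).any()

    def test_shared_target_passes_same_rank(self):
        g = nx.Graph([("T", "B"), ("T", "C")])
        net = InteractionNetwork(
            graph=g, tractable={n: True for n in g.nodes},
            analyte_map={"T_P1": "T", "B_P1": "B", "C_P1": "C"},
        )
        profile = PerturbationProfile("S", "anchor_t", {"T_P1": 0, "B_P1": 1.0, "C_P1": 0.5})
        from phosphoresponse.core import PerturbationMatrix, AnalytePanel
        matrix = PerturbationMatrix.from_profiles(
            [profile], AnalytePanel(("B_P1", "C_P1", "T_P1", "GAPDH"))
        )
        table = compute_eps_table(matrix, net)
        drugs = [
            DrugInfo("anchor_t", ("T",)),
            DrugInfo("d1", ("B",)),
            DrugInfo("d2", ("B",)),
        ]
        noms = nominate_combinations(table, drugs, net, k=5)
        block = noms[noms["anchor"] == "anchor_t"]
        assert set(block.loc[block["partner"].isin(["d1", "d2"]), "rank"]) == {
            block["rank"].min()
        }


class TestConcordance:
    def test_reported_fraction_arithmetic(self):
        assert ConcordanceResult(128, 73, 5, 0.1).percent == 57
        assert ConcordanceResult(128, 106, 10, 0.1).percent == 83

    def test_rank_one_everywhere_gives_fraction_one(self, small_cohort):
        c = small_cohort
        # raise threshold so only planted (hot, rank <= 5) pairs remain
        res = topk_concordance(
            c.eps_table, c.screen.bliss_summary, c.drug_targets, c.network,
            bliss_threshold=0.15, k=5,
        )
        assert res.fraction == pytest.approx(1.0)

    def test_threshold_above_all_scores_undefined_fraction(self, small_cohort):
        c = small_cohort
        res = topk_concordance(
            c.eps_table, c.screen.bliss_summary, c.drug_targets, c.network,
            bliss_threshold=99.0,
        )
        assert res.n_synergistic == 0 and res.fraction is None and res.percent is None

    def test_random_ranks_hit_at_k_over_n_rate(self):
        """Null calibration: with uniformly random ranks over 20 tractable
        entities, the top-5 hit rate is 25% within a binomial interval."""
        rng = np.random.default_rng(0)
        n_entities, k, trials = 20, 5, 2000
        hits = sum(
            rng.permutation(n_entities)[0] + 1 <= k for _ in range(trials)
        )
        rate = hits / trials
        se = np.sqrt(0.25 * 0.75 / trials)
        assert abs(rate - 0.25) < 4 * se


class TestNetworkIO:
    def test_round_trip(self, tmp_path, small_cohort):
        net = small_cohort.network
        paths = [tmp_path / p for p in ("edges.tsv", "tract.tsv", "map.tsv")]
        write_network(net, *paths)
        back = read_network(*paths)
        assert {tuple(sorted(e)) for e in back.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }
        assert back.tractable == net.tractable
        assert back.analyte_map == net.analyte_map

    def test_self_loop_rejected(self):
        g = nx.Graph([("A", "A")])
        with pytest.raises(ValueError, match="self-loop"):
            InteractionNetwork(graph=g, tractable={}, analyte_map={})
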