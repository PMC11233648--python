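import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from spikenet.motifs import (
    classify_triad,
    motif_catalog,
    motif_intensity_census,
    motif_overlap,
    motif_zscores,
    mask_outlier_replicates,
    pair_census,
    pair_relative_counts,
    pfflb_sets,
)

from _oracles import census_oracle
from conftest import random_signed_network


@pytest.fixture(scope="module")
def cat3():
    return motif_catalog(3, signed=True)


class TestCatalog:
    def test_thirteen_unsigned_triads(self):
        cat = motif_catalog(3, signed=False)
        assert len(cat.classes) == 13

    def test_two_node_classes(self):
        assert len(motif_catalog(2, signed=False).classes) == 2
        signed = motif_catalog(2, signed=True)
        assert len(signed.classes) == 5
        assert sum(c.n_edges == 2 for c in signed.classes) == 3

    def test_ffl_containing_classes_and_mutual_groups(self):
        cat = motif_catalog(3, signed=False)
        ffl = [c for c in cat.classes if c.contains_ffl]
        assert len(ffl) == 6
        assert sorted({c.n_mutual for c in ffl}) == [0, 1, 2, 3]
        # the feedforward loop itself: 3 edges, no mutual pair, class 6
        pure = [c for c in ffl if c.n_mutual == 0]
        assert len(pure) == 1 and pure[0].id == "6" and pure[0].n_edges == 3

    def test_every_labelled_triad_maps_to_exactly_one_class(self, cat3):
        # exhaustive over all 3^6 signed labelled digraphs
        unsigned = motif_catalog(3, signed=False)
        n_connected = 0
        for code in range(3**6):
            idx = cat3.code_to_class[code]
            digits = []
            c = code
            for _ in range(6):
                c, d = divmod(c, 3)
                digits.append(d)
            ucode = sum((1 if d else 0) << i for i, d in enumerate(digits))
            uidx = unsigned.code_to_class[ucode]
            assert (idx >= 0) == (uidx >= 0)
            if idx >= 0:
                n_connected += 1
                assert (
                    cat3.classes[idx].unsigned_id
                    == unsigned.classes[uidx].unsigned_id
                )
        assert n_connected > 0

    def test_pfflb_flag_matches_containment_search(self, cat3):
        # independent subgraph-containment check for the all-positive
        # transitive triangle on each canonical pattern
        for cls in cat3.classes:
            digits = []
            c = cls.canonical_code
            for _ in range(6):
                c, d = divmod(c, 3)
                digits.append(d)
            pos = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
            sign = {p: d for p, d in zip(pos, digits)}
            found = any(
                sign[(a, b)] == 1 and sign[(b, c_)] == 1 and sign[(a, c_)] == 1
                for a, b, c_ in itertools.permutations(range(3), 3)
            )
            assert cls.contains_pffl == found


class TestClassify:
    def test_all_positive_ffl_is_p6(self, cat3):
        g = nx.DiGraph()
        for u, v in [("A", "B"), ("B", "C"), ("A", "C")]:
            g.add_edge(u, v, sign=1, weight=1.0)
        uid, sid = classify_triad(g, ["A", "B", "C"], cat3)
        assert uid == 6 and sid == "p6"
        # invariance under permutation of the node names
        assert classify_triad(g, ["C", "A", "B"], cat3) == (6, "p6")

    def test_disconnected_triple_is_not_a_motif(self, cat3):
        g = nx.DiGraph()
        g.add_edge("A", "B", sign=1, weight=1.0)
        g.add_node("C")
        assert classify_triad(g, ["A", "B", "C"], cat3) is None


class TestCensus:
    def test_counts_equal_intensity_for_unit_weights(self, cat3):
        g = random_signed_network(n_nodes=15, density=0.2, seed=3)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(np.sign(d["weight"]) or 1.0)
        tab = motif_intensity_census(g, cat3)
        assert np.allclose(tab["count"], tab["intensity"])

    def test_single_ffl_geometric_mean(self, cat3):
        g = nx.DiGraph()
        g.add_edge(0, 1, sign=1, weight=1.0)
        g.add_edge(1, 2, sign=1, weight=2.0)
        g.add_edge(0, 2, sign=1, weight=4.0)
        tab = motif_intensity_census(g, cat3)
        assert tab.loc["p6", "count"] == 1
        assert tab.loc["p6", "intensity"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_random_network(self, cat3):
        g = random_signed_network(n_nodes=30, density=0.15, seed=9)
        tab = motif_intensity_census(g, cat3)
        oracle = census_oracle(g)
        assert tab["count"].sum() == sum(c for c, _ in oracle.values())
        assert tab["intensity"].sum() == pytest.approx(
            sum(s for _, s in oracle.values()), abs=1e-9
        )
        # per-class: number of distinct oracle keys with nonzero count must
        # equal the number of nonzero catalog classes
        assert (tab["count"] > 0).sum() == len(oracle)

    def test_census_conservation(self, cat3):
        g = random_signed_network(n_nodes=20, density=0.2, seed=4)
        tab = motif_intensity_census(g, cat3)
        und = nx.Graph(g.to_undirected())
        n_connected = sum(
            1
            for tri in itertools.combinations(g.nodes, 3)
            if nx.is_connected(und.subgraph(tri))
            and und.subgraph(tri).number_of_edges() >= 2
        )
        assert tab["count"].sum() == n_connected

    def test_empty_network(self, cat3):
        g = nx.DiGraph()
        g.add_nodes_from(range(5))
        tab = motif_intensity_census(g, cat3)
        assert (tab["count"] == 0).all()


class TestZScores:
    def test_degenerate_ensemble_scores_zero_or_flagged(self, cat3, signed_net):
        tab = motif_zscores(signed_net, [signed_net] * 10, cat3)
        assert tab["degenerate"].all()
        assert np.allclose(tab["zscore"], 0.0)

    def test_planted_reciprocal_pairs_show_in_er_relative_count(self):
        rng = np.random.default_rng(1)
        g = nx.DiGraph()
        g.add_nodes_from(range(20))
        pairs = [(u, v) for u, v in itertools.combinations(range(20), 2)]
        for u, v in [pairs[i] for i in rng.choice(len(pairs), 15, replace=False)]:
            g.add_edge(u, v, sign=1, weight=1.0)
            g.add_edge(v, u, sign=1, weight=1.0)
        from spikenet.nulls import SurrogateSpec, surrogate_ensemble

        ens = surrogate_ensemble(g, SurrogateSpec(kind="erdos_renyi", n=100, seed=2))
        tab = pair_relative_counts(g, ens)
        assert tab.loc["p2", "ratio"] > 1.0

    def test_er_closed_form_expectation(self):
        # reciprocal-count expectation in a density-matched random digraph is
        # C(n,2) * p^2; a network with every edge reciprocated exceeds it
        g = nx.DiGraph()
        g.add_nodes_from(range(16))
        for u in range(0, 16, 2):
            g.add_edge(u, u + 1, sign=1, weight=1.0)
            g.add_edge(u + 1, u, sign=1, weight=1.0)
        n, e = 16, 16
        p = e / (n * (n - 1))
        expected_recip = n * (n - 1) / 2 * p * p
        from spikenet.nulls import SurrogateSpec, surrogate_ensemble

        ens = surrogate_ensemble(g, SurrogateSpec(kind="erdos_renyi", n=300, seed=0))
        counts = [pair_census(h)[["p2", "2m1", "n2"]].sum() for h in ens]
        assert np.mean(counts) == pytest.approx(expected_recip, rel=0.25)
        assert 8 / np.mean(counts) > 1.0

    def test_planted_positive_ffls_rank_among_top_z(self, cat3):
        """All-positive FFLs planted on a random signed background are
        over-represented against the signed-pair-preserving reference in a
        majority of seeds."""
        from spikenet.nulls import SurrogateSpec, surrogate_ensemble

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            g = random_signed_network(n_nodes=24, density=0.08, seed=700 + seed)
            rng = np.random.default_rng(seed)
            planted = rng.choice(24, size=9, replace=False)
            for t in range(3):
                a, b, c = planted[3 * t : 3 * t + 3]
                for u, v in [(a, b), (b, c), (a, c)]:
                    g.add_edge(int(u), int(v), sign=1, weight=1.0)
            ens = surrogate_ensemble(
                g, SurrogateSpec(kind="signed_pair_preserving", n=100, seed=seed)
            )
            ztab = motif_zscores(g, ens, cat3)
            z = ztab["zscore"].replace([np.inf, -np.inf], np.nan).dropna()
            top5 = set(z.sort_values(ascending=False).head(5).index)
            wins += "p6" in top5
        assert wins > n_seeds / 2

    def test_outlier_masking_across_replicates(self):
        z = pd.DataFrame(
            {"p6": [1.0, 1.1, 0.9, 1.0, 0.95, 1.05, 25.0], "p1": [0.0] * 7}
        )
        keep = mask_outlier_replicates(z)
        assert not keep.loc[6, "p6"]
        assert keep["p6"][:6].all() and keep["p1"].all()


class TestPFFLb:
    def test_planted_same_area_fraction(self, cat3):
        g = nx.DiGraph()
        for u in "abc":
            g.add_node(u, area="V1")
        g.add_edge("a", "b", sign=1, weight=1.0)
        g.add_edge("b", "c", sign=1, weight=1.0)
        g.add_edge("a", "c", sign=1, weight=1.0)
        sets = pfflb_sets(g, cat3, area="V1")
        assert sets["p6"].frac_all_in_area == 1.0
        assert sets["p6"].frac_any_in_area == 1.0

    def test_no_positive_edges_means_empty_sets(self, cat3):
        g = nx.DiGraph()
        g.add_nodes_from("abcd", area="V1")
        g.add_edge("a", "b", sign=-1, weight=-1.0)
        g.add_edge("b", "c", sign=-1, weight=-1.0)
        g.add_edge("a", "c", sign=-1, weight=-1.0)
        sets = pfflb_sets(g, cat3, area="V1")
        assert all(len(s.instances) == 0 for s in sets.values())
        assert all(s.frac_any_in_area is None for s in sets.values())

    def test_fractions_equal_hand_tally(self, cat3):
        g = nx.DiGraph()
        for u, area in zip("abcdef", ["V1", "V1", "V1", "LM", "LM", "LM"]):
            g.add_node(u, area=area)
        for tri in [("a", "b", "c"), ("a", "d", "e"), ("d", "e", "f")]:
            g.add_edge(tri[0], tri[1], sign=1, weight=1.0)
            g.add_edge(tri[1], tri[2], sign=1, weight=1.0)
            g.add_edge(tri[0], tri[2], sign=1, weight=1.0)
        sets = pfflb_sets(g, cat3, area="V1")
        p6 = sets["p6"]
        assert len(p6.instances) == 3
        assert p6.frac_any_in_area == pytest.approx(2 / 3)
        assert p6.frac_all_in_area == pytest.approx(1 / 3)


class TestOverlap:
    def test_identical_and_disjoint_sets(self):
        a = {("p6", ("x", "y", "z"))}
        tab = motif_overlap({"s1": a, "s2": set(a)})
        exact = {tuple(r.conditions): r.count for r in tab.itertuples()}
        assert exact[("s1", "s2")] == 1
        assert exact[("s1",)] == 0 and exact[("s2",)] == 0
        tab = motif_overlap({"s1": a, "s2": {("p6", ("q", "r", "s"))}})
        exact = {tuple(r.conditions): r.count for r in tab.itertuples()}
        assert exact[("s1",)] == 1 and exact[("s2",)] == 1
        assert exact[("s1", "s2")] == 0

    def test_hand_enumeration(self):
        s1 = {"abc", "abd", "bcd"}
        s2 = {"abd", "bcd", "cde"}
        tab = motif_overlap({"A": s1, "B": s2})
        exact = {tuple(r.conditions): r.count for r in tab.itertuples()}
        assert exact[("A", "B")] == 2
        assert exact[("A",)] == 1 and exact[("B",)] == 1
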