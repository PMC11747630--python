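import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from benthocouple import (
    align_graphs,
    alignment_quality,
    coupling_summary,
    graphlet_degree_vectors,
    hiveplot_layout,
    sequence_similarity,
    shared_families,
    topo_similarity,
)
from benthocouple.graph_alignment import AlignmentResult, _objective


def brute_force_best(net_a, net_b, seqsim, alpha):
    """Exhaustive search over all partial injective mappings."""
    na, nb = sorted(net_a.nodes()), sorted(net_b.nodes())
    max_pairs = min(len(na), len(nb))
    best = 0.0
    for k in range(1, max_pairs + 1):
        for dom in itertools.combinations(na, k):
            for img in itertools.permutations(nb, k):
                j = _objective(net_a, net_b, seqsim, dict(zip(dom, img)), alpha, max_pairs)
                best = max(best, j)
    return best


def _random_pair(inst):
    rng = np.random.default_rng(inst)
    na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
    ga = nx.relabel_nodes(
        nx.gnp_random_graph(na, 0.5, seed=int(rng.integers(10**6))), lambda i: f"a{i}"
    )
    gb = nx.relabel_nodes(
        nx.gnp_random_graph(nb, 0.5, seed=int(rng.integers(10**6))), lambda i: f"b{i}"
    )
    seqsim = pd.DataFrame(rng.random((na, nb)), index=sorted(ga), columns=sorted(gb))
    return ga, gb, seqsim


class TestSequenceSimilarity:
    def test_identical_sequences_score_one(self):
        s = "ACGT" * 95
        sim = sequence_similarity({"p": s}, {"b": s})
        assert sim.loc["p", "b"] == 1.0

    def test_single_substitution_in_hundred(self):
        a = "ACGT" * 25
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        sim = sequence_similarity({"p": a}, {"b": b})
        assert sim.loc["p", "b"] == pytest.approx(0.99)

    def test_reverse_complement_scores_low(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            s = "".join(rng.choice(list("ACGT"), 120))
            rc = "".join(comp[c] for c in reversed(s))
            vals.append(sequence_similarity({"p": s}, {"b": rc}).iloc[0, 0])
        assert np.mean(vals) < 0.6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sequence_similarity({"p": ""}, {"b": "ACGT"})


class TestGraphletSignatures:
    def test_star_orbits(self):
        g = nx.star_graph(3)  # center 0 + 3 leaves: one claw graphlet
        gdv = graphlet_degree_vectors(g)
        assert gdv.loc[0, "orbit_0"] == 3  # degree
        assert gdv.loc[0, "orbit_7"] == 1  # claw centre
        assert gdv.loc[1, "orbit_6"] == 1  # claw leaf
        assert gdv.loc[0, "orbit_3"] == 0  # no triangles

    def test_triangle_orbits(self):
        g = nx.complete_graph(3)
        gdv = graphlet_degree_vectors(g)
        assert (gdv["orbit_3"] == 1).all()
        assert (gdv["orbit_1"] == 0).all()

    def test_k4_orbit(self):
        gdv = graphlet_degree_vectors(nx.complete_graph(4))
        assert (gdv["orbit_14"] == 1).all()
        assert (gdv["orbit_12"] == 0).all()

    def test_path4_orbits(self):
        g = nx.path_graph(4)
        gdv = graphlet_degree_vectors(g)
        assert gdv.loc[0, "orbit_4"] == 1  # path end
        assert gdv.loc[1, "orbit_5"] == 1  # path middle

    def test_cycle_and_diamond(self):
        gdv_c = graphlet_degree_vectors(nx.cycle_graph(4))
        assert (gdv_c["orbit_8"] == 1).all()
        diamond = nx.complete_graph(4)
        diamond.remove_edge(0, 1)
        gdv_d = graphlet_degree_vectors(diamond)
        assert gdv_d.loc[0, "orbit_12"] == 1  # degree-2 corner
        assert gdv_d.loc[2, "orbit_13"] == 1  # degree-3 hub


class TestTopoSimilarity:
    def test_isomorphic_graphs_corresponding_nodes_identical(self):
        g1 = nx.relabel_nodes(nx.cycle_graph(5), lambda i: f"a{i}")
        g2 = nx.relabel_nodes(nx.cycle_graph(5), lambda i: f"b{i}")
        sim = topo_similarity(g1, g2)
        assert np.allclose(sim.to_numpy(), 1.0)

    def test_hub_more_similar_to_hub_than_to_leaf(self):
        g1 = nx.relabel_nodes(nx.star_graph(5), lambda i: f"a{i}")
        g2 = nx.relabel_nodes(nx.star_graph(5), lambda i: f"b{i}")
        sim = topo_similarity(g1, g2)
        assert sim.loc["a0", "b0"] > sim.loc["a0", "b1"]

    def test_single_edge_graphs_fully_similar(self):
        g1 = nx.Graph([("a0", "a1")])
        g2 = nx.Graph([("b0", "b1")])
        assert np.allclose(topo_similarity(g1, g2).to_numpy(), 1.0)

    def test_isolated_nodes_have_defined_similarity(self):
        g1 = nx.Graph()
        g1.add_node("a0")
        g2 = nx.Graph([("b0", "b1")])
        sim = topo_similarity(g1, g2)
        assert np.isfinite(sim.to_numpy()).all()


class TestAlignmentQuality:
    def test_identity_on_identical_graphs(self):
        g = nx.cycle_graph(5)
        ec, s3 = alignment_quality(g, g, {i: i for i in g})
        assert ec == 1.0 and s3 == 1.0

    def test_no_preserved_edges(self):
        ga = nx.Graph([(0, 1)])
        gb = nx.Graph([(0, 1), (2, 3)])
        ec, s3 = alignment_quality(ga, gb, {0: 0, 1: 2})
        assert ec == 0.0 and s3 == 0.0

    def test_triangle_onto_path_hand_count(self):
        tri = nx.complete_graph(3)
        path = nx.path_graph(3)
        # map triangle onto the path: 2 of 3 edges conserved, no extras
        ec, s3 = alignment_quality(tri, path, {0: 0, 1: 1, 2: 2})
        assert ec == pytest.approx(2 / 3)
        assert s3 == pytest.approx(2 / 3)

    def test_s3_never_exceeds_ec(self):
        for inst in range(20):
            ga, gb, _ = _random_pair(inst)
            nodes = sorted(ga)[: min(len(ga), len(gb))]
            mapping = dict(zip(nodes, sorted(gb)))
            ec, s3 = alignment_quality(ga, gb, mapping)
            assert s3 <= ec + 1e-12

    def test_non_injective_mapping_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="injective"):
            alignment_quality(g, g, {0: 0, 1: 0})


class TestAlignGraphs:
    def test_identical_graphs_identity_sequence_prior(self):
        g = nx.relabel_nodes(nx.les_miserables_graph().subgraph(
            list(nx.les_miserables_graph())[:8]
        ).copy(), str)
        if g.number_of_edges() == 0:
            g = nx.relabel_nodes(nx.cycle_graph(8), str)
        ss = pd.DataFrame(np.eye(len(g)), index=sorted(g), columns=sorted(g))
        res = align_graphs(g, g, ss, alpha=0.4, seed=0)
        assert res.mapping == {n: n for n in g}
        assert res.ec == 1.0 and res.s3 == 1.0

    def test_alpha_one_reduces_to_rowwise_argmax(self):
        rng = np.random.default_rng(0)
        ga = nx.relabel_nodes(nx.path_graph(4), lambda i: f"a{i}")
        gb = nx.relabel_nodes(nx.cycle_graph(4), lambda i: f"b{i}")
        base = rng.random((4, 4)) * 0.3
        for i, j in enumerate([1, 3, 0, 2]):
            base[i, j] = 0.9  # distinct argmax per row
        ss = pd.DataFrame(base, index=sorted(ga), columns=sorted(gb))
        res = align_graphs(ga, gb, ss, alpha=1.0, seed=0)
        for i, u in enumerate(sorted(ga)):
            assert res.mapping[u] == ss.columns[np.argmax(base[i])]

    def test_alpha_zero_ignores_sequence_labels(self):
        ga, gb, ss = _random_pair(3)
        res1 = align_graphs(ga, gb, ss, alpha=0.0, seed=0)
        perm = np.random.default_rng(0).permutation(ss.shape[1])
        ss_perm = pd.DataFrame(ss.to_numpy()[:, perm], index=ss.index, columns=ss.columns)
        res2 = align_graphs(ga, gb, ss_perm, alpha=0.0, seed=0)
        assert res1.mapping == res2.mapping
        assert res1.objective == pytest.approx(res2.objective)

    @pytest.mark.parametrize("inst", range(12))
    def test_near_optimal_on_small_instances(self, inst):
        ga, gb, ss = _random_pair(inst)
        alpha = [0.0, 0.4, 1.0][inst % 3]
        res = align_graphs(ga, gb, ss, alpha=alpha, seed=inst)
        best = brute_force_best(ga, gb, ss, alpha)
        assert res.objective >= 0.95 * best - 1e-9

    def test_empty_network_gives_empty_alignment(self):
        res = align_graphs(nx.Graph(), nx.path_graph(3), None, alpha=0.4, seed=0)
        assert res.mapping == {} and res.objective == 0.0

    def test_bad_alpha_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="alpha"):
            align_graphs(g, g, None, alpha=1.5, seed=0)


class TestCouplingSummary:
    def _result(self, pairs, seqsims):
        table = pd.DataFrame(
            [
                {"pelagic_id": u, "benthic_id": v, "node_similarity": 1.0, "seq_similarity": s}
                for (u, v), s in zip(pairs, seqsims)
            ],
            columns=["pelagic_id", "benthic_id", "node_similarity", "seq_similarity"],
        )
        return AlignmentResult(dict(pairs), 0.4, 1.0, 1.0, 1.0, table)

    def _tax(self, ids, divisions):
        return pd.DataFrame(
            {
                "division": divisions,
                "class": ["c"] * len(ids),
                "order": ["o"] * len(ids),
                "family": ["f"] * len(ids),
                "genus": ["g"] * len(ids),
                "species": ["s"] * len(ids),
            },
            index=ids,
        )

    def test_identity_alignment_full_concordance(self):
        ids = ["x", "y"]
        tax = self._tax(ids, ["Diatomea", "Cercozoa"])
        res = self._result([("x", "x"), ("y", "y")], [1.0, 1.0])
        summary = coupling_summary(res, tax, tax, 2, 2)
        assert summary["fraction_same_division"] == 1.0
        assert summary["aligned_nodes"] == 2
        assert len(summary["self_aligned"]) == 2

    def test_empty_alignment_zero_counts(self):
        res = AlignmentResult({}, 0.4, 0.0, 0.0, 0.0, pd.DataFrame(
            columns=["pelagic_id", "benthic_id", "node_similarity", "seq_similarity"]
        ))
        summary = coupling_summary(res, None, None, 5, 7)
        assert summary["aligned_nodes"] == 0
        assert summary["possible_nodes"] == 5
        assert summary["fraction_same_division"] == 0.0

    def test_flow_table_matches_hand_tally(self):
        tax_a = self._tax(["p1", "p2", "p3"], ["Diatomea", "Diatomea", "Cercozoa"])
        tax_b = self._tax(["b1", "b2", "b3"], ["Diatomea", "Metazoa", "Cercozoa"])
        res = self._result([("p1", "b1"), ("p2", "b2"), ("p3", "b3")], [0.9, 0.5, 0.4])
        summary = coupling_summary(res, tax_a, tax_b, 3, 3)
        flow = summary["flow_table"].set_index(["pelagic_division", "benthic_division"])
        assert flow.loc[("Diatomea", "Diatomea"), "n_asvs"] == 1
        assert flow.loc[("Diatomea", "Metazoa"), "n_asvs"] == 1
        assert summary["fraction_same_division"] == pytest.approx(2 / 3)

    def test_shared_families_venn(self):
        tax_a = self._tax(["p1", "p2"], ["D", "D"])
        tax_a["family"] = ["f1", "f2"]
        tax_b = self._tax(["b1", "b2"], ["D", "D"])
        tax_b["family"] = ["f2", "f3"]
        venn = shared_families(tax_a, tax_b)
        assert venn == {
            "only_a": 1,
            "only_b": 1,
            "shared": 1,
            "shared_names": ["f2"],
        }


class TestHiveplot:
    def test_layout_matches_manual_construction(self):
        ga = nx.Graph([("p1", "p2"), ("p2", "p3")])
        gb = nx.Graph([("b1", "b2")])
        res = AlignmentResult(
            {"p1": "b1"},
            0.4,
            1.0,
            1.0,
            1.0,
            pd.DataFrame(
                [{"pelagic_id": "p1", "benthic_id": "b1", "node_similarity": 1.0, "seq_similarity": 1.0}]
            ),
        )
        ab_a = pd.Series({"p1": 0.5, "p2": 0.3, "p3": 0.2})
        ab_b = pd.Series({"b1": 0.9, "b2": 0.1})
        layout = hiveplot_layout(ga, gb, res, ab_a, ab_b).set_index("node")
        assert layout.loc["p1", "abundance_rank"] == 1
        assert layout.loc["p1", "group"] == "internal"
        assert layout.loc["p2", "group"] == "external"
        assert layout.loc["b1", "group"] == "internal"
        assert layout.loc["p2", "size"] == pytest.approx(1.0)  # degree 2 of 2
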