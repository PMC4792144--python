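import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from oracles import gotoh_local
from wrkyfam.errors import FormatError
from wrkyfam.homology import (aggregate_pair_totals, all_vs_all_scores,
                              build_similarity_graph, call_pair_types,
                              homolog_groups, local_align_score, mcl,
                              pair_count_table, reciprocal_best_hits,
                              wrky_density, TypedPair)
from wrkyfam.io_formats import ProteinRecord
from wrkyfam.synthetic_data import simulate_family_evolution

AA = list("ACDEFGHIKLMNPQRSTVWY")
BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestLocalAlignment:
    def test_self_score_is_diagonal_sum(self):
        seq = "WRKYGQKAVILDE"
        expected = sum(float(BLOSUM62[r][r]) for r in seq)
        assert local_align_score(seq, seq) == pytest.approx(expected)

    def test_unrelated_low_similarity_sequences_score_zero(self):
        # no positive substitution scores between glycine runs and tryptophan
        assert local_align_score("GGGGG", "WWWWW") == 0.0

    def test_matches_brute_force_dp_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a = "".join(rng.choice(AA, size=rng.integers(1, 13)))
            b = "".join(rng.choice(AA, size=rng.integers(1, 13)))
            assert local_align_score(a, b) == pytest.approx(gotoh_local(a, b))
            assert local_align_score(a, b) == local_align_score(b, a)


class TestSimilarityGraph:
    def _records(self, seqs):
        return [ProteinRecord(id=f"p{i}", sequence=s, species="X")
                for i, s in enumerate(seqs)]

    def test_duplicate_sequences_weight_one(self):
        g = build_similarity_graph(self._records(["WRKYGQKAVIL"] * 2))
        assert g.edges["p0", "p1"]["weight"] == pytest.approx(1.0)

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(1)
        records = self._records(
            ["".join(rng.choice(AA, size=30)) for _ in range(8)])
        g = build_similarity_graph(records, cutoff=0.0)
        for _, _, data in g.edges(data=True):
            assert 0 < data["weight"] <= 1.0

    def test_cutoff_one_keeps_only_equal_self_score_pairs(self):
        records = self._records(["WRKYGQKAVIL", "WRKYGQKAVIL", "DDEEDDEEDDE"])
        g = build_similarity_graph(records, cutoff=1.0)
        assert set(g.edges) == {("p0", "p1")}

    def test_no_self_edges(self):
        g = build_similarity_graph(self._records(["WRKY", "WRKY"]))
        assert not any(u == v for u, v in g.edges)


class TestMcl:
    def _clique_graph(self, groups, bridges=()):
        g = nx.Graph()
        for nodes in groups:
            for a, b in itertools.combinations(nodes, 2):
                g.add_edge(a, b, weight=1.0)
        for a, b, w in bridges:
            g.add_edge(a, b, weight=w)
        return g

    def test_disjoint_triangles_two_clusters(self):
        g = self._clique_graph([("a", "b", "c"), ("d", "e", "f")])
        assert mcl(g) == [{"a", "b", "c"}, {"d", "e", "f"}]

    def test_weakly_bridged_cliques_split_at_inflation_two(self):
        g = self._clique_graph([("a", "b", "c"), ("d", "e", "f")],
                               bridges=[("c", "d", 0.05)])
        assert mcl(g, inflation=2.0) == [{"a", "b", "c"}, {"d", "e", "f"}]

    def test_clusters_partition_nodes(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        clusters = mcl(g)
        seen = [n for c in clusters for n in c]
        assert sorted(seen) == sorted(g.nodes)
        assert len(seen) == len(set(seen))

    def test_empty_graph(self):
        assert mcl(nx.Graph()) == []

    def test_invariant_under_relabeling(self):
        g = self._clique_graph([(0, 1, 2, 3), (4, 5, 6)],
                               bridges=[(3, 4, 0.1)])
        mapping = {i: f"node{(i * 7) % 11}" for i in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        base = mcl(g, inflation=2.0)
        shuffled = mcl(relabeled, inflation=2.0)
        assert sorted(frozenset(mapping[n] for n in c) for c in base) == \
               sorted(frozenset(c) for c in shuffled)


class TestRbh:
    def _scores(self, mat, ids):
        return pd.DataFrame(mat, index=ids, columns=ids, dtype=float)

    def test_single_gene_pair_with_positive_score(self):
        scores = self._scores([[10, 4], [4, 8]], ["a1", "b1"])
        species = {"a1": "A", "b1": "B"}
        assert reciprocal_best_hits(scores, species, "A", "B") == {("a1", "b1")}

    def test_asymmetric_best_hit_excluded(self):
        # b1's best in A is a2, but a2's best in B is b2
        ids = ["a1", "a2", "b1", "b2"]
        mat = np.zeros((4, 4))
        mat[0, 2] = mat[2, 0] = 5    # a1-b1
        mat[1, 2] = mat[2, 1] = 9    # a2-b1
        mat[1, 3] = mat[3, 1] = 12   # a2-b2
        scores = self._scores(mat, ids)
        species = dict(zip(ids, "AABB"))
        pairs = reciprocal_best_hits(scores, species, "A", "B")
        # b1 -> a2 is one-directional (a2 prefers b2), and a1 -> b1 is
        # one-directional too (b1 prefers a2): only (a2, b2) is reciprocal
        assert pairs == {("a2", "b2")}

    def test_matches_exhaustive_check_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            na, nb = rng.integers(2, 5, size=2)
            ids = [f"a{i}" for i in range(na)] + [f"b{j}" for j in range(nb)]
            species = {g: g[0].upper() for g in ids}
            mat = np.zeros((na + nb, na + nb))
            block = rng.integers(1, 20, size=(na, nb)).astype(float)
            mat[:na, na:] = block
            mat[na:, :na] = block.T
            scores = self._scores(mat, ids)
            pairs = reciprocal_best_hits(scores, species, "A", "B")
            expected = set()
            for i in range(na):
                for j in range(nb):
                    if block[i, j] == block[i].max() and \
                       block[i, j] == block[:, j].max():
                        expected.add((f"a{i}", f"b{j}"))
            assert pairs == expected


class TestPairTyping:
    def test_same_species_cluster_paralog(self):
        pairs = call_pair_types([{"a1", "a2"}], {"a1": "A", "a2": "A"}, set())
        assert [(p.type,) for p in pairs] == [("paralog",)]

    def test_cross_species_rbh_ortholog(self):
        pairs = call_pair_types([{"a1", "b1"}], {"a1": "A", "b1": "B"},
                                {("a1", "b1")})
        assert pairs[0].type == "ortholog"

    def test_three_gene_cluster_enumeration(self):
        species = {"a1": "A", "a2": "A", "b1": "B"}
        pairs = call_pair_types([{"a1", "a2", "b1"}], species, {("a1", "b1")})
        types = {frozenset((p.a, p.b)): p.type for p in pairs}
        assert types == {
            frozenset(("a1", "a2")): "paralog",
            frozenset(("a1", "b1")): "ortholog",
            frozenset(("a2", "b1")): "coortholog",
        }

    def test_every_pair_typed_exactly_once(self):
        species = {f"{s}{i}": s.upper() for s in "abc" for i in range(3)}
        cluster = set(species)
        pairs = call_pair_types([cluster], species, set())
        assert len(pairs) == len(cluster) * (len(cluster) - 1) // 2


class TestPairTable:
    ORDER = ("A", "B", "C")

    def test_empty_pairs_zero_table(self):
        table = pair_count_table([], {}, self.ORDER)
        assert aggregate_pair_totals(table) == (0, 0, 0)

    def test_counts_and_conservation(self):
        species = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        pairs = [TypedPair("a1", "a2", "paralog"),
                 TypedPair("a1", "b1", "ortholog"),
                 TypedPair("a2", "b1", "coortholog"),
                 TypedPair("a1", "c1", "ortholog")]
        table = pair_count_table(pairs, species, self.ORDER)
        assert table.diagonal == {"A": 1, "B": 0, "C": 0}
        assert table.cells[("B", "A")] == (1, 1)
        assert table.cells[("C", "A")] == (1, 0)
        totals = aggregate_pair_totals(table)
        assert sum(totals) == len(pairs)

    def test_fixture_totals(self, table2):
        assert aggregate_pair_totals(table2) == (543, 452, 677)


class TestDensity:
    def test_closed_form(self):
        assert wrky_density(10, 100.0) == pytest.approx(0.1)

    def test_inversion_consistency_with_printed_density(self):
        # family of 95 at 0.1979 per Mb implies a ~480 Mb genome
        implied_mb = 95 / 0.1979
        assert wrky_density(95, implied_mb) == pytest.approx(0.1979, abs=5e-5)

    def test_linear_in_count(self):
        assert wrky_density(20, 50.0) == pytest.approx(2 * wrky_density(10, 50.0))


class TestFamilyRecovery:
    def test_ortholog_precision_and_recall_on_simulated_families(self):
        records, truth = simulate_family_evolution(sub_prob=0.05, seed=0)
        result = homolog_groups(records)
        called = {frozenset((p.a, p.b)): p.type for p in result.typed_pairs}
        true_orth = {k for k, v in truth.pair_types.items() if v == "ortholog"}
        called_orth = {k for k, v in called.items() if v == "ortholog"}
        tp = len(true_orth & called_orth)
        assert tp / len(called_orth) >= 0.9   # precision
        assert tp / len(true_orth) >= 0.9     # recall

    def test_clusters_respect_simulated_families(self):
        records, truth = simulate_family_evolution(n_families=8, seed=1)
        result = homolog_groups(records)
        for cluster in result.clusters:
            fams = {truth.families[g] for g in cluster}
            assert len(fams) == 1
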