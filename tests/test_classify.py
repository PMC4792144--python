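import numpy as np
import pandas as pd
import pytest

from oracles import (enumerate_unrooted_topologies, gotoh_global,
                     pdistance_pair, topology_fits_additively, topology_splits)
from wrkyfam.classify import (MSA, ReferenceSet, Tree, assign_subgroup,
                              bootstrap_support, center_star_msa,
                              classify_by_rule, classify_family,
                              neighbor_joining, pairwise_identity,
                              pdistance_matrix, summarize_family,
                              members_from_table1)
from wrkyfam.domain_scan import assemble_domains
from wrkyfam.errors import FormatError
from wrkyfam.synthetic_data import gen_subgroup_queries, gen_wrky_protein

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_tree_distances(n, seed):
    """Additive distances from a random binary tree with known splits."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    edges = None
    for candidate in [enumerate_unrooted_topologies(taxa)[0]]:
        edges = candidate
    # randomize: pick a random topology instead of the first
    all_topos = enumerate_unrooted_topologies(taxa)
    edges = all_topos[rng.integers(len(all_topos))]
    import networkx as nx
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, length=float(rng.uniform(0.5, 2.0)))
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        lengths = nx.single_source_dijkstra_path_length(g, a, weight="length")
        for b in taxa[i + 1:]:
            d.loc[a, b] = d.loc[b, a] = lengths[b]
    return d, topology_splits(edges, taxa)


class TestRuleClassification:
    def test_one_c2hc_domain_is_group_iii(self):
        rec, _ = gen_wrky_protein("III", seed=2)
        assert classify_by_rule(assemble_domains(rec.sequence)) == ("III", False)

    def test_two_c2h2_domains_is_group_i(self):
        rec, _ = gen_wrky_protein("I", seed=2)
        assert classify_by_rule(assemble_domains(rec.sequence)) == ("I", False)

    def test_one_c2h2_domain_is_group_ii(self):
        rec, _ = gen_wrky_protein("II", seed=2)
        assert classify_by_rule(assemble_domains(rec.sequence)) == ("II", False)

    def test_no_domains_unclassified(self):
        assert classify_by_rule([]) == ("unclassified", False)

    def test_multi_domain_with_c2hc_flagged(self):
        rec1, _ = gen_wrky_protein("II", seed=5)
        rec3, _ = gen_wrky_protein("III", seed=6)
        domains = assemble_domains(rec1.sequence + rec3.sequence)
        assert len(domains) == 2
        assert classify_by_rule(domains) == ("I", True)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("WRKYGQK", "WRKYGQK") == 1.0

    def test_empty_sequence_is_error(self):
        with pytest.raises(FormatError):
            pairwise_identity("", "WRKY")

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = "".join(rng.choice(AA, size=rng.integers(3, 15)))
            b = "".join(rng.choice(AA, size=rng.integers(3, 15)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = "".join(rng.choice(AA, size=10))
            b = "".join(rng.choice(AA, size=10))
            assert 0.0 <= pairwise_identity(a, b) <= 1.0


class TestCenterStar:
    def test_identical_sequences_gapless(self):
        msa = center_star_msa({"a": "WRKY", "b": "WRKY", "c": "WRKY"}, "a")
        assert set(msa.rows) == {"WRKY"}

    def test_insertion_creates_gap_columns(self):
        anchor = "WRKYGQKDDEE"
        withins = anchor[:5] + "PPP" + anchor[5:]
        msa = center_star_msa({"a": anchor, "b": withins, "c": anchor}, "a")
        assert msa.n_columns == len(anchor) + 3
        assert msa.row("a").count("-") == 3
        assert msa.row("b").count("-") == 0

    def test_missing_anchor_is_error(self):
        with pytest.raises(FormatError):
            center_star_msa({"a": "WRKY"}, "zzz")

    def test_column_count_at_least_anchor_length(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seqs = {f"s{i}": "".join(rng.choice(AA, size=rng.integers(8, 20)))
                    for i in range(4)}
            msa = center_star_msa(seqs, "s0")
            assert msa.n_columns >= len(seqs["s0"])
            assert len({len(r) for r in msa.rows}) == 1


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MSA(ids=("a", "b"), rows=("WRKY", "WRKY"))
        assert pdistance_matrix(msa).to_numpy().max() == 0.0

    def test_closed_form(self):
        msa = MSA(ids=("a", "b"), rows=("AAAAAAAAAA", "AAAAAAAACC"))
        assert pdistance_matrix(msa).loc["a", "b"] == pytest.approx(0.2)

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            cols = int(rng.integers(5, 30))
            rows = tuple("".join(rng.choice(AA + ["-"], size=cols))
                         for _ in range(4))
            ids = tuple(f"r{i}" for i in range(4))
            try:
                ours = pdistance_matrix(MSA(ids=ids, rows=rows))
            except FormatError:
                continue
            for i in range(4):
                for j in range(i + 1, 4):
                    assert ours.iloc[i, j] == pytest.approx(
                        pdistance_pair(rows[i], rows[j]))

    def test_zero_comparable_columns_is_error(self):
        msa = MSA(ids=("a", "b"), rows=("A---", "---C"))
        with pytest.raises(FormatError):
            pdistance_matrix(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("ijk"), columns=list("ijk"), dtype=float)
        tree = neighbor_joining(d)
        dist = tree.distances_from("i")
        center = next(n for n in tree.graph.nodes if n not in set("ijk"))
        assert tree.graph.edges["i", center]["length"] == pytest.approx(1.0)
        assert tree.graph.edges["j", center]["length"] == pytest.approx(2.0)
        assert tree.graph.edges["k", center]["length"] == pytest.approx(3.0)

    def test_fewer_than_three_taxa_is_error(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(FormatError):
            neighbor_joining(d)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_vs_exhaustive_enumeration(self, n):
        """NJ must return the unique topology that fits the distances
        additively, found by scanning every unrooted topology."""
        for seed in range(4):
            d, true_splits = _random_tree_distances(n, seed=100 * n + seed)
            taxa = list(d.index)
            fitting = [topology_splits(t, taxa)
                       for t in enumerate_unrooted_topologies(taxa)
                       if topology_fits_additively(t, d, taxa)]
            assert len({frozenset(s) for s in fitting}) == 1
            assert neighbor_joining(d).bipartitions() == fitting[0]
            assert fitting[0] == true_splits

    @pytest.mark.parametrize("n", [7, 8])
    def test_additive_recovery_larger_trees(self, n):
        for seed in range(3):
            d, true_splits = _random_tree_distances(n, seed=7000 + 10 * n + seed)
            assert neighbor_joining(d).bipartitions() == true_splits

    def test_agrees_with_reference_nj_implementation(self):
        """On additive matrices (where the NJ topology is determined) our
        tree matches scikit-bio's independent neighbor-joining."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for seed in range(3):
            d, _ = _random_tree_distances(7, seed=900 + seed)
            ours = neighbor_joining(d).bipartitions()
            ref_tree = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
            theirs = set()
            names = set(d.index)
            anchor = min(names)
            for node in ref_tree.non_tips(include_self=True):
                side = {t.name for t in node.tips()}
                if anchor in side:
                    side = names - side
                if 2 <= len(side) <= len(names) - 2:
                    theirs.add(frozenset(side))
            assert ours == theirs

    def test_taxon_permutation_gives_isomorphic_tree(self):
        d, _ = _random_tree_distances(6, seed=42)
        perm = list(np.random.default_rng(5).permutation(list(d.index)))
        shuffled = d.loc[perm, perm]
        assert neighbor_joining(d).bipartitions() == \
               neighbor_joining(shuffled).bipartitions()


class TestBootstrap:
    def _two_clade_msa(self):
        rng = np.random.default_rng(9)
        left = "".join(rng.choice(AA, size=60))
        right = "".join(rng.choice(AA, size=60))

        def jitter(base, k):
            chars = list(base)
            for pos in rng.choice(60, size=3, replace=False):
                chars[pos] = str(rng.choice(AA))
            return "".join(chars)

        ids = ("l1", "l2", "l3", "r1", "r2", "r3")
        rows = (jitter(left, 0), jitter(left, 1), jitter(left, 2),
                jitter(right, 0), jitter(right, 1), jitter(right, 2))
        return MSA(ids=ids, rows=rows)

    def test_clear_clades_get_high_support(self):
        msa = self._two_clade_msa()
        supports = bootstrap_support(msa, n_replicates=200, seed=0)
        split = frozenset({"r1", "r2", "r3"})
        assert split in supports
        assert supports[split] >= 0.95

    def test_same_seed_reproducible(self):
        msa = self._two_clade_msa()
        assert bootstrap_support(msa, 50, seed=3) == \
               bootstrap_support(msa, 50, seed=3)

    def test_degenerate_alignment_warns_and_zeroes(self):
        msa = MSA(ids=("a", "b", "c", "d"), rows=("WRKY",) * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            supports = bootstrap_support(msa, 10, seed=0)
        assert all(v == 0.0 for v in supports.values())


class TestSubgroupAssignment:
    def test_zero_distance_reference_wins(self, reference_set):
        seqs = dict(reference_set.sequences)
        seqs["query"] = seqs["ref_IIc"]
        msa = center_star_msa(seqs, "ref_I")
        dist = pdistance_matrix(msa)
        assert assign_subgroup(dist, "query", reference_set) == "IIc"

    def test_tie_broken_by_three_nearest_majority(self):
        refs = ReferenceSet(entries=(
            ("r1", "IIa", "WRKYGQKAAAA"), ("r2", "IIb", "WRKYGQKCCCC"),
            ("r3", "IIa", "WRKYGQKDDDD")))
        dist = pd.DataFrame(
            [[0, 1, 1, 2], [1, 0, 2, 2], [1, 2, 0, 2], [2, 2, 2, 0]],
            index=["q", "r1", "r2", "r3"], columns=["q", "r1", "r2", "r3"],
            dtype=float)
        # r1 (IIa) and r2 (IIb) tie at distance 1; third nearest is IIa
        assert assign_subgroup(dist, "q", refs) == "IIa"

    def test_empty_reference_set_is_error(self):
        with pytest.raises(FormatError):
            assign_subgroup(pd.DataFrame(), "q", ReferenceSet(entries=()))

    def test_synthetic_queries_recover_template_subgroup(self, reference_set):
        queries, truth = gen_subgroup_queries(6, 0.10, seed=11)
        fam = classify_family(queries, reference_set, n_bootstrap=0)
        hits = sum(c.subgroup == truth[c.gene_id] for c in fam.calls)
        assert hits / len(fam.calls) >= 0.9


class TestClassifyFamily:
    def test_synthetic_cohort_full_group_recovery(self, reference_set):
        records, expected = [], {}
        for i, group in enumerate(["I", "II", "III"] * 10):
            rec, _ = gen_wrky_protein(group, seed=500 + i,
                                      record_id=f"p{i}", )
            records.append(rec)
            expected[rec.id] = group
        fam = classify_family(records, reference_set, n_bootstrap=0)
        assert len(fam) == 30
        for call in fam.calls:
            assert call.provisional_group == expected[call.gene_id]

    def test_empty_input_empty_table(self, reference_set):
        fam = classify_family([], reference_set)
        assert len(fam) == 0

    def test_c2hc_near_ii_reference_flagged_not_overridden(self, reference_set):
        # group-III architecture grafted onto the IIc reference body:
        # the rule says III, the phylogeny says IIc -> conflict flag set,
        # neither call silently overridden
        iic = reference_set.sequences["ref_IIc"]
        # template layout: anchor(7) linker(5) C s1(4) C s2(23) H s3(1) H
        seq = iic[:17] + "AAA" + iic[17:43] + "C"
        from wrkyfam.io_formats import ProteinRecord
        rec = ProteinRecord(id="oddball", sequence=seq)
        (call,) = classify_family([rec], reference_set, n_bootstrap=0).calls
        assert call.provisional_group == "III"
        assert call.conflict_flag
        assert call.subgroup == "IIc"


class TestSummaries:
    def test_fixture_group_counts(self, table1):
        summary = summarize_family(members_from_table1(table1))
        assert summary.n_members == 95
        assert summary.group_counts["I"] == 17
        assert summary.group_counts["II"] == 67
        assert summary.group_counts["III"] == 11

    def test_fixture_variant_counts(self, table1):
        summary = summarize_family(members_from_table1(table1))
        assert summary.variant_counts["WRKYGQK"] == 88
        assert sum(v for k, v in summary.variant_counts.items()
                   if k != "WRKYGQK") == 7

    def test_fixture_length_range(self, table1):
        summary = summarize_family(members_from_table1(table1))
        assert summary.length_min == 101
        assert summary.length_max == 865
        assert summary.length_mean_1dp == round(summary.length_mean, 1)
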