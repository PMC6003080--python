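import numpy as np
import pandas as pd
import pytest

from hfe.core import (
    HFEResult,
    aggregate_taxa,
    correlation_filter,
    ig_leaf_filter,
    ig_path_filter,
    run_hfe,
)
from hfe.io import AbundanceTable, LabelVector
from hfe.synthetic import simulate
from hfe.taxonomy import Lineage, build_tree


def _table(columns, rows, samples=None):
    samples = samples or [f"S{i}" for i in range(len(rows))]
    return AbundanceTable(
        pd.DataFrame(rows, index=samples, columns=columns), normalized=True
    )


class TestAggregation:
    def test_taxon_column_is_sum_of_children(self, three_otu_table, three_otu_tree):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        genus = three_otu_tree.otu_attachment["OTU1"].id
        family = three_otu_tree.otu_attachment["OTU3"].id
        v = three_otu_table.data
        assert np.allclose(ext.data[genus], v["OTU1"] + v["OTU2"])
        # family children are the genus subtree AND the incomplete leaf
        assert np.allclose(ext.data[family], v["OTU1"] + v["OTU2"] + v["OTU3"])

    def test_single_kingdom_aggregate_is_one(self, three_otu_table, three_otu_tree):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        assert np.allclose(ext.data["k__Bacteria"], 1.0, atol=1e-9)

    def test_feature_space_grows_to_m_plus_m_prime(self, three_otu_table, three_otu_tree):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        assert ext.n_features == three_otu_tree.m + three_otu_tree.m_prime
        # OTU columns pass through untouched
        pd.testing.assert_frame_equal(
            ext.data[three_otu_table.feature_ids], three_otu_table.data
        )

    def test_unknown_feature_rejected(self, three_otu_tree):
        bad = _table(["OTU1", "OTU9"], [[0.5, 0.5]])
        with pytest.raises(ValueError, match="OTU9"):
            aggregate_taxa(bad, three_otu_tree)


class TestCorrelationFilter:
    def _pair_tree(self):
        # one genus with a single OTU child under it via species
        return build_tree(
            ["O1"], {"O1": Lineage(("B", "P", "C", "O", "F", "G", "S"))}
        )

    def test_identical_child_discarded(self):
        tree = self._pair_tree()
        table = _table(["O1"], [[1.0], [2.0], [3.0], [4.0]])
        ext = aggregate_taxa(table, tree)
        retained, s1 = correlation_filter(ext, tree, 0.7)
        # every internal chain column equals the OTU: all children of every
        # parent correlate at 1 and are discarded, leaving only the kingdom
        assert retained == ["k__B"]
        assert s1 == 7

    def test_anticorrelated_child_kept(self):
        tree = build_tree(
            ["O1", "O2"],
            {
                "O1": Lineage(("B", "P", "C", "O", "F", "G", "S1")),
                "O2": Lineage(("B", "P", "C", "O", "F", "G", "S2")),
            },
        )
        rows = [[0.1, 0.9], [0.2, 0.8], [0.3, 0.7], [0.4, 0.6]]
        ext = aggregate_taxa(_table(["O1", "O2"], rows), tree)
        retained, s1 = correlation_filter(ext, tree, 0.7)
        s1_id = tree.otu_attachment["O1"].id
        s2_id = tree.otu_attachment["O2"].id
        # each species tracks its single OTU (rho=1, OTUs discarded), but the
        # two species anticorrelate with the constant genus (rho undefined -> 0)
        assert s1_id in retained and s2_id in retained
        assert "O1" not in retained and "O2" not in retained

    def test_zero_variance_parent_keeps_child(self):
        tree = self._pair_tree()
        # genus column constant, OTU varies: undefined Pearson counts as 0
        table = _table(["O1"], [[1.0]] * 4, samples=list("abcd"))
        ext = aggregate_taxa(table, tree)
        # all columns constant here; every rho undefined -> everything kept
        retained, s1 = correlation_filter(
            AbundanceTable(ext.data * 0.0, normalized=False), tree, 0.7
        )
        assert s1 == 0

    def test_closed_form_pearson_below_threshold_keeps_child(self):
        # parent (1,2,3,4,10) vs child (1,2,3,4,0): rho = -2/sqrt(20) ~ -0.447
        parent = np.array([1, 2, 3, 4, 10.0])
        child = np.array([1, 2, 3, 4, 0.0])
        rho = -2.0 / np.sqrt(20.0)
        assert np.isclose(np.corrcoef(parent, child)[0, 1], rho)
        tree = build_tree(
            ["O1", "O2"],
            {
                "O1": Lineage(("B", "P", "C", "O", "F", "G", "S1")),
                "O2": Lineage(("B", "P", "C", "O", "F", "G", "S2")),
            },
        )
        sibling = parent - child  # makes the genus aggregate equal `parent`
        rows = np.column_stack([child, sibling])
        ext = aggregate_taxa(
            AbundanceTable(
                pd.DataFrame(rows, index=list("abcde"), columns=["O1", "O2"]),
                normalized=False,
            ),
            tree,
        )
        retained, _ = correlation_filter(ext, tree, 0.7)
        assert tree.otu_attachment["O1"].id in retained  # species1 == O1 vs genus

    def test_theta_validated(self, three_otu_table, three_otu_tree):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        for bad in (0.0, 1.0, -0.3, 2.0):
            with pytest.raises(ValueError):
                correlation_filter(ext, three_otu_tree, bad)

    def test_s1_monotone_in_theta(self):
        table, labels, tree, _ = simulate(n_otus=60, n_samples=30, seed=3)
        ext = aggregate_taxa(table, tree)
        s1s = [correlation_filter(ext, tree, th)[1] for th in (0.3, 0.5, 0.7, 0.9)]
        assert s1s == sorted(s1s, reverse=True)


def _path_fixture():
    """Two OTUs under different genera of one family, plus engineered columns."""
    tree = build_tree(
        ["O1", "O2"],
        {
            "O1": Lineage(("B", "P", "C", "O", "F", "G1", "S1")),
            "O2": Lineage(("B", "P", "C", "O", "F", "G2", "S2")),
        },
    )
    return tree


class TestPathFilter:
    def test_zero_ig_nodes_always_discarded(self, three_otu_table, three_otu_tree, four_sample_labels):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        ig = {f: 0.0 for f in ext.feature_ids}
        ig["OTU1"] = 1.0
        kept, s2, avg = ig_path_filter(
            list(ext.feature_ids), ext, three_otu_tree, four_sample_labels, ig=ig
        )
        assert kept == ["OTU1"]
        assert avg == 1.0

    def test_equal_positive_ig_all_kept(self, three_otu_table, three_otu_tree, four_sample_labels):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        ig = {f: 0.4 for f in ext.feature_ids}
        kept, s2, avg = ig_path_filter(
            list(ext.feature_ids), ext, three_otu_tree, four_sample_labels, ig=ig
        )
        # incomplete leaf OTU3 is exempt (deferred to phase 4), all others tie at the mean
        assert set(kept) == set(ext.feature_ids) - {"OTU3"}
        assert s2 == 0

    def test_node_shared_by_two_paths_kept_if_it_passes_on_either(self, four_sample_labels):
        tree = _path_fixture()
        g1 = tree.otu_attachment["O1"].parent.id  # genus of O1
        table = _table(
            ["O1", "O2"], [[0.5, 0.5]] * 4, samples=["S1", "S2", "S3", "S4"]
        )
        ext = aggregate_taxa(table, tree)
        shared = tree.nodes[g1].parent.id  # family node, on both paths
        # on path 1 the shared family (ig .3) fails vs mean of {.3, .9, ...};
        # engineered so it passes on path 2
        ig = {f: 0.0 for f in ext.feature_ids}
        ig[shared] = 0.3
        ig[g1] = 0.9
        ig["O1"] = 0.9
        kept, s2, _ = ig_path_filter(
            list(ext.feature_ids), ext, tree, four_sample_labels, ig=ig
        )
        # path O2: nodes {k,p,c,o,family,g2,s2,O2} have ig 0 except family ->
        # family mean on that path is low and family passes there
        assert shared in kept

    def test_global_averaging_strategy(self, three_otu_table, three_otu_tree, four_sample_labels):
        ext = aggregate_taxa(three_otu_table, three_otu_tree)
        ig = {f: 0.0 for f in ext.feature_ids}
        ig["OTU1"] = 0.6
        ig["OTU2"] = 0.02  # below the global mean (~0.07) over all candidates
        kept, _, _ = ig_path_filter(
            list(ext.feature_ids), ext, three_otu_tree, four_sample_labels,
            average="global", ig=ig,
        )
        assert "OTU1" in kept and "OTU2" not in kept
        with pytest.raises(ValueError):
            ig_path_filter(
                list(ext.feature_ids), ext, three_otu_tree, four_sample_labels,
                average="median", ig=ig,
            )


class TestLeafFilter:
    def test_zero_ig_leaf_discarded_even_with_zero_threshold(self, three_otu_table, four_sample_labels):
        kept, s3 = ig_leaf_filter(
            ["OTU3"], three_otu_table, four_sample_labels, 0.0, ig={"OTU3": 0.0}
        )
        assert kept == [] and s3 == 1

    def test_leaf_at_exactly_global_average_kept(self, three_otu_table, four_sample_labels):
        kept, s3 = ig_leaf_filter(
            ["OTU3"], three_otu_table, four_sample_labels, 0.5, ig={"OTU3": 0.5}
        )
        assert kept == ["OTU3"] and s3 == 0

    def test_leaves_straddling_average_split(self, three_otu_table, four_sample_labels):
        kept, s3 = ig_leaf_filter(
            ["a", "b"], three_otu_table, four_sample_labels, 0.5,
            ig={"a": 0.8, "b": 0.2},
        )
        assert kept == ["a"] and s3 == 1


class TestRunHfe:
    def test_count_identity_and_determinism(self):
        table, labels, tree, _ = simulate(n_otus=80, n_samples=40, seed=9)
        r1 = run_hfe(table, labels, tree)
        r2 = run_hfe(table, labels, tree)
        assert r1.selected == r2.selected
        assert r1.ig_scores == r2.ig_scores
        assert len(r1.selected) == tree.m + tree.m_prime - r1.s1 - r1.s2 - r1.s3

    def test_redundant_otus_pruned_perfect_genus_kept(self):
        # two OTUs that each perfectly track their genus aggregate, and the
        # genus separates the classes: OTUs go in phase 2, genus survives
        tree = build_tree(
            ["O1", "O2"],
            {
                "O1": Lineage(("B", "P", "C", "O", "F", "G", "S")),
                "O2": Lineage(("B", "P", "C", "O", "F", "G", "S")),
            },
        )
        lo, hi = 0.1, 0.4
        rows = [[lo, lo], [lo, lo], [hi, hi], [hi, hi]]
        rows = [[a, b] for a, b in rows]
        table = AbundanceTable(
            pd.DataFrame(
                [[a, b, 1 - a - b] for a, b in rows],
                index=["S1", "S2", "S3", "S4"],
                columns=["O1", "O2", "O3"],
            ),
            normalized=True,
        )
        tree = build_tree(
            ["O1", "O2", "O3"],
            {
                "O1": Lineage(("B", "P", "C", "O", "F", "G", "S")),
                "O2": Lineage(("B", "P", "C", "O", "F", "G", "S")),
                "O3": Lineage(("B", "P2", "C2", "O2", "F2", "G2", "S2")),
            },
        )
        labels = LabelVector({"S1": "x", "S2": "x", "S3": "y", "S4": "y"})
        result = run_hfe(table, labels, tree)
        # member OTUs are redundant with their lineage aggregate and pruned;
        # a single ancestor of the separating clade survives with IG 1 bit
        assert "O1" not in result.selected and "O2" not in result.selected
        survivors = [f for f in result.selected if ";p__P;" in f or f.endswith(";p__P")]
        assert len(survivors) == 1
        assert result.ig_scores[survivors[0]] == 1.0

    def test_permuted_labels_select_almost_nothing(self):
        table, labels, tree, _ = simulate(seed=21)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.sample_ids)
        shuffled = LabelVector(
            {s: labels.mapping[p] for s, p in zip(table.sample_ids, perm)}
        )
        result = run_hfe(table, shuffled, tree)
        assert len(result.selected) <= 0.05 * (tree.m + tree.m_prime)

    def test_single_otu_single_rank_tree(self):
        tree = build_tree(["O1"], {"O1": Lineage(("B",))})
        table = _table(["O1"], [[1.0]] * 4)
        labels = LabelVector({"S0": "x", "S1": "x", "S2": "y", "S3": "y"})
        result = run_hfe(table, labels, tree)
        assert len(result.selected) == tree.m + tree.m_prime - result.s1 - result.s2 - result.s3

    def test_unnormalized_table_rejected(self, three_otu_tree, four_sample_labels):
        raw = _table(["OTU1", "OTU2", "OTU3"], [[1.0, 2.0, 3.0]] * 4)
        raw.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            run_hfe(raw, four_sample_labels, three_otu_tree)

    def test_result_invariant_enforced(self):
        with pytest.raises(AssertionError):
            HFEResult(
                selected=("a",), ig_scores={"a": 0.1},
                s1=0, s2=0, s3=0, theta=0.7, m=3, m_prime=2,
            )
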