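"""Diversity metrics against brute-force branch tabulations and closed forms."""

import io as _io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from oracles import brute_force_faith_pd, brute_force_unifrac
from wildgut import diversity
from wildgut.errors import UsageError, ValidationError
from wildgut.io import OtuTable


class TestAlpha:
    def test_uniform_four_taxa(self, three_leaf_tree):
        tree = TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        tab = OtuTable(pd.DataFrame({"s": [5, 5, 5, 5]}, index=list("ABCD")))
        rec = diversity.alpha_diversity(tab, tree).iloc[0]
        assert rec["observed_otus"] == 4
        assert rec["shannon"] == pytest.approx(2.0)

    def test_single_taxon_sample(self, three_leaf_tree):
        tab = OtuTable(pd.DataFrame({"s": [0, 0, 4]}, index=list("ABC")))
        rec = diversity.alpha_diversity(tab, three_leaf_tree).iloc[0]
        assert rec["shannon"] == 0.0
        assert rec["faith_pd"] == pytest.approx(2.0)  # root-to-C path

    def test_all_leaves_pd_is_total_length(self, three_leaf_tree, small_table):
        recs = diversity.alpha_diversity(small_table, three_leaf_tree)
        # s2 observes B and C only
        assert recs.loc[recs["sample_id"] == "s1", "faith_pd"].iloc[0] == pytest.approx(
            brute_force_faith_pd(three_leaf_tree, {"A", "C"})
        )

    def test_missing_taxon_named(self, three_leaf_tree):
        tab = OtuTable(pd.DataFrame({"s": [1, 1]}, index=["A", "GHOST"]))
        with pytest.raises(ValidationError, match="GHOST"):
            diversity.alpha_diversity(tab, three_leaf_tree)

    def test_pd_monotone_in_observed_taxa(self, three_leaf_tree):
        subsets = [{"A"}, {"A", "B"}, {"A", "B", "C"}]
        pds = [brute_force_faith_pd(three_leaf_tree, s) for s in subsets]
        tabs = [
            OtuTable(
                pd.DataFrame(
                    {"s": [1 if x in s else 0 for x in "ABC"]}, index=list("ABC")
                )
            )
            for s in subsets
        ]
        got = [
            diversity.alpha_diversity(t, three_leaf_tree)["faith_pd"].iloc[0]
            for t in tabs
        ]
        assert got == pytest.approx(pds)
        assert got[0] <= got[1] <= got[2]


class TestUnifrac:
    def test_worked_three_leaf_example(self, three_leaf_tree, small_table):
        expected = {
            "unweighted": 0.4,
            "weighted_raw": 5 / 3,
            "weighted_normalized": 5 / 12,
        }
        for mode, val in expected.items():
            dm = diversity.unifrac(small_table, three_leaf_tree, mode)
            assert dm["s1", "s2"] == pytest.approx(val)
            assert dm["s1", "s2"] == pytest.approx(
                brute_force_unifrac(
                    three_leaf_tree, {"A": 2, "C": 1}, {"B": 3, "C": 1}, mode
                )
            )

    @pytest.mark.parametrize("mode", diversity.UNIFRAC_MODES)
    def test_identical_samples_distance_zero(self, three_leaf_tree, mode):
        tab = OtuTable(pd.DataFrame({"s1": [2, 1, 3], "s2": [2, 1, 3]}, index=list("ABC")))
        assert diversity.unifrac(tab, three_leaf_tree, mode)["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_halves_of_star_unweighted_one(self):
        tree = TreeNode.read(_io.StringIO("((A:1,B:1):0.5,(C:1,D:1):0.5);"))
        tab = OtuTable(
            pd.DataFrame({"s1": [3, 2, 0, 0], "s2": [0, 0, 1, 4]}, index=list("ABCD"))
        )
        assert diversity.unifrac(tab, tree, "unweighted")["s1", "s2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", diversity.UNIFRAC_MODES)
    @pytest.mark.parametrize("seed", range(4))
    def test_random_tables_match_brute_force(self, mode, seed):
        """Enumerated <= 5-leaf trees vs. the per-branch oracle."""
        rng = np.random.default_rng(seed)
        leaves = list("ABCDE")[: rng.integers(3, 6)]
        newick = None
        # random caterpillar with random lengths
        parts = [f"{x}:{rng.uniform(0.1, 2):.3f}" for x in leaves]
        while len(parts) > 1:
            a, b = parts.pop(), parts.pop()
            parts.append(f"({a},{b}):{rng.uniform(0.1, 2):.3f}")
        newick = parts[0].rsplit(":", 1)[0] + ";"
        tree = TreeNode.read(_io.StringIO(newick))
        counts = rng.integers(0, 9, size=(len(leaves), 2))
        counts[rng.integers(len(leaves)), 0] += 1
        counts[rng.integers(len(leaves)), 1] += 1
        tab = OtuTable(pd.DataFrame(counts, index=leaves, columns=["s1", "s2"]))
        got = diversity.unifrac(tab, tree, mode)["s1", "s2"]
        want = brute_force_unifrac(
            tree,
            dict(zip(leaves, counts[:, 0])),
            dict(zip(leaves, counts[:, 1])),
            mode,
        )
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("mode", diversity.UNIFRAC_MODES)
    def test_metric_axioms_on_simulated_study(self, small_config, mode):
        from wildgut.simulate import simulate_study

        study = simulate_study(small_config, seed=3)
        dm = diversity.unifrac(study.table, study.tree, mode)
        assert (dm.data >= 0).all()
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        if mode != "weighted_raw":
            assert dm.data.max() <= 1 + 1e-9

    def test_unrooted_tree_rejected(self, small_table):
        tree = TreeNode.read(_io.StringIO("(A:1,B:1,C:2);"))
        with pytest.raises(ValidationError, match="rooted"):
            diversity.unifrac(small_table, tree, "unweighted")


class TestAggregation:
    def test_single_phylum_is_one(self, small_taxonomy):
        tab = OtuTable(pd.DataFrame({"s": [3, 7]}, index=["A", "B"]))
        out = diversity.aggregate_rank(tab, small_taxonomy, "phylum")
        assert out.loc["Firmicutes", "s"] == pytest.approx(1.0)

    def test_sixty_forty_split(self, small_taxonomy):
        tab = OtuTable(pd.DataFrame({"s": [40, 20, 40]}, index=["A", "B", "C"]))
        out = diversity.aggregate_rank(tab, small_taxonomy, "phylum")
        assert out.loc["Firmicutes", "s"] == pytest.approx(0.6)
        assert out.loc["Bacteroidetes", "s"] == pytest.approx(0.4)

    def test_unknown_rank_pools_to_unassigned(self, small_taxonomy):
        tab = OtuTable(pd.DataFrame({"s": [1, 1]}, index=["A", "Zzz"]))
        out = diversity.aggregate_rank(tab, small_taxonomy, "phylum")
        assert diversity.UNASSIGNED in out.index

    @pytest.mark.parametrize("rank", ["phylum", "genus"])
    def test_conservation_on_random_tables(self, small_config, rank):
        from wildgut.simulate import simulate_study

        study = simulate_study(small_config, seed=9)
        out = diversity.aggregate_rank(study.table, study.taxonomy, rank)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)


class TestFbRatio:
    def _phylum_table(self, f, b):
        df = pd.DataFrame({"s": [f, b, 1 - f - b]},
                          index=["Firmicutes", "Bacteroidetes", "Other"])
        df.index.name = "phylum"
        return df

    def test_two_to_one(self):
        out = diversity.fb_ratio(self._phylum_table(0.6, 0.3))
        assert out["ratio"].iloc[0] == pytest.approx(2.0)

    def test_equal_is_one(self):
        out = diversity.fb_ratio(self._phylum_table(0.4, 0.4))
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_bacteroidetes_undefined(self):
        out = diversity.fb_ratio(self._phylum_table(0.6, 0.0))
        assert np.isnan(out["ratio"].iloc[0])

    def test_wrong_rank_rejected(self):
        df = pd.DataFrame({"s": [1.0]}, index=["Firmicutes"])
        df.index.name = "genus"
        with pytest.raises(UsageError):
            diversity.fb_ratio(df)


class TestPcoa:
    def _euclidean_dm(self, points, ids=None):
        import skbio

        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        return skbio.DistanceMatrix(d, ids=ids or [f"p{i}" for i in range(len(points))])

    def test_line_recovered_on_first_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])
        res = diversity.pcoa(self._euclidean_dm(pts), axes=3)
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.sort(np.diff(np.sort(axis1)))  # reflection-invariant
        assert gaps == pytest.approx([1.0, 1.0, 3.0], abs=1e-9)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_equilateral_three_points(self):
        import skbio

        dm = skbio.DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        res = diversity.pcoa(dm, axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        recov = np.sqrt(
            ((res.coordinates.to_numpy()[:, None] - res.coordinates.to_numpy()[None]) ** 2).sum(-1)
        )
        assert recov[np.triu_indices(3, 1)] == pytest.approx([1, 1, 1], abs=1e-9)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 4))
        dm = self._euclidean_dm(pts)
        res = diversity.pcoa(dm, axes=7)
        coords = res.coordinates.to_numpy()
        recov = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.abs(recov - dm.data).max() < 1e-9

    def test_matches_independent_implementation(self):
        """Cross-check eigenvalues against scikit-bio's ordination."""
        import skbio
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        dm = self._euclidean_dm(pts)
        ours = diversity.pcoa(dm, axes=3)
        theirs = skbio_pcoa(dm, number_of_dimensions=3)
        assert ours.eigenvalues[:3] == pytest.approx(
            np.asarray(theirs.eigvals)[:3], abs=1e-8
        )

    def test_axes_bound(self):
        dm = self._euclidean_dm(np.zeros((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(UsageError):
            diversity.pcoa(dm, axes=3)
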