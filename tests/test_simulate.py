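"""Synthetic study generator: determinism, design fidelity, planted structure."""

import numpy as np
import pandas as pd
import pytest

from wildgut import diversity
from wildgut.kinship import PedigreeGraph
from wildgut.simulate import (
    SimulationConfig,
    consensus_benchmark_config,
    null_config,
    simulate_metadata,
    simulate_pedigree,
    simulate_study,
    simulate_tree,
)


class TestPedigree:
    def test_depth_one_all_founders(self):
        cfg = SimulationConfig(pedigree_generations=1, founder_fraction=1.0)
        records, info = simulate_pedigree(cfg, seed=0)
        assert all(r.sire_id is None and r.dam_id is None for r in records)

    def test_wild_individuals_are_isolated_founders(self, default_study):
        ped = PedigreeGraph(default_study.pedigree)
        meta = default_study.metadata
        wild = meta.loc[meta["population"] == "wild", "individual_id"]
        for ind in wild:
            assert ped.parents(ind) == {}
        # and relatedness to any captive individual is 0
        captive = meta.loc[meta["population"] == "SHWP", "individual_id"].iloc[0]
        assert ped.kinship_index(wild.iloc[0], captive) == 0.0

    def test_same_seed_identical(self):
        cfg = SimulationConfig()
        r1, i1 = simulate_pedigree(cfg, seed=5)
        r2, i2 = simulate_pedigree(cfg, seed=5)
        assert r1 == r2
        pd.testing.assert_frame_equal(i1, i2)

    def test_full_sib_pairs_have_kinship_half(self, default_study):
        ped = PedigreeGraph(default_study.pedigree)
        sibs = {}
        for rec in default_study.pedigree:
            if rec.sire_id and rec.dam_id:
                sibs.setdefault((rec.sire_id, rec.dam_id), []).append(rec.individual_id)
        full_sib_pairs = [v for v in sibs.values() if len(v) >= 2]
        assert full_sib_pairs, "generator should produce at least one full sibship"
        checked = 0
        for group in full_sib_pairs[:5]:
            a, b = group[:2]
            k = ped.kinship_index(a, b)
            # parents may themselves be related, so K >= 0.5
            assert k >= 0.5 - 1e-12
            checked += 1
        assert checked > 0

    def test_sires_male_dams_female(self, default_study):
        info = pd.DataFrame(
            [{"individual": r.individual_id, "sire": r.sire_id, "dam": r.dam_id}
             for r in default_study.pedigree]
        )
        sex = default_study.metadata.set_index("individual_id")["sex"]
        for _, row in info.dropna().iterrows():
            assert sex[row["sire"]] == "M"
            assert sex[row["dam"]] == "F"


class TestTree:
    def test_two_taxa_single_cherry(self):
        cfg = SimulationConfig(taxa_per_phylum=1,
                               phylum_shifts={"A": 0.0, "B": 0.0})
        tree = simulate_tree(cfg, seed=1)
        assert len(list(tree.tips())) == 2

    def test_leaf_count_matches_config(self):
        cfg = SimulationConfig(taxa_per_phylum=5)
        tree = simulate_tree(cfg, seed=2)
        assert len(list(tree.tips())) == cfg.n_taxa

    def test_phylum_blocks_are_clades(self, default_study):
        from wildgut.simulate import taxon_catalog

        catalog = taxon_catalog(default_study.config)
        tree = default_study.tree
        firm = set(catalog.loc[catalog["phylum"] == "Firmicutes", "taxon"])
        lca = tree.lca(list(firm))
        assert {t.name for t in lca.tips()} == firm

    def test_same_seed_identical_newick(self):
        cfg = SimulationConfig(taxa_per_phylum=4)
        assert str(simulate_tree(cfg, seed=9)) == str(simulate_tree(cfg, seed=9))


class TestStudy:
    def test_default_design_population_sizes(self, default_study):
        sizes = default_study.metadata["population"].value_counts().to_dict()
        assert sizes == {
            "wild": 10, "wild_fed": 14, "CDZ": 7, "BJZ": 3, "BJWP": 24,
            "NJZ": 6, "SHWP": 33, "SHZ": 17, "HZZ": 9,
        }
        assert default_study.metadata["population"].nunique() == 9

    def test_status_wild_only_for_wild(self, default_study):
        meta = default_study.metadata
        assert (meta["status"] == "wild").sum() == 10
        assert set(meta.loc[meta["population"] == "wild_fed", "status"]) == {"AD"}

    def test_counts_match_truth_and_conserve(self, default_study):
        truth = default_study.truth
        assert set(truth.taxa["taxon"]) == set(default_study.table.taxon_ids)
        assert truth.taxa["planted"].sum() == default_study.config.n_planted_genera
        totals = default_study.table.counts.sum(axis=0)
        lo, hi = default_study.config.depth_range
        assert ((totals >= lo) & (totals <= hi)).all()

    def test_same_seed_byte_identical_files(self, tmp_path, small_config):
        simulate_study(small_config, seed=3, out_dir=tmp_path / "a")
        simulate_study(small_config, seed=3, out_dir=tmp_path / "b")
        for name in ("otu_table.tsv", "taxonomy.tsv", "tree.nwk", "metadata.tsv",
                     "pedigree.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_files_round_trip_through_io(self, tmp_path, small_config):
        from wildgut import io as wio

        study = simulate_study(small_config, seed=4, out_dir=tmp_path)
        tab, _ = wio.read_otu_table(study.paths["otu_table"])
        pd.testing.assert_frame_equal(tab.counts, study.table.counts,
                                      check_names=False)
        tax = wio.read_taxonomy(study.paths["taxonomy"])
        assert tax.covers(tab.taxon_ids)
        tree = wio.read_tree(study.paths["tree"])
        assert {t.name for t in tree.tips()} == set(tab.taxon_ids)
        meta = wio.read_metadata(study.paths["metadata"])
        assert list(meta["sample_id"]) == tab.sample_ids
        ped = wio.read_pedigree(study.paths["pedigree"])
        assert {r.individual_id for r in ped} >= set(meta["individual_id"])

    def test_null_config_zeroes_everything(self):
        cfg = null_config()
        assert all(v == 0 for v in cfg.phylum_shifts.values())
        assert cfg.heritability == 0 and cfg.population_effect_sd == 0

    def test_benchmark_config_planted_count(self):
        cfg = consensus_benchmark_config()
        study = simulate_study(cfg, seed=6)
        assert study.truth.taxa["planted"].sum() == 12
        assert (study.truth.taxa.loc[~study.truth.taxa["planted"], "ad_shift"] == 0).all()


class TestPlantedEffects:
    def test_ad_fb_ratio_below_wild(self, default_study):
        """The planted phylum shifts push the AD-group F/B ratio down."""
        abund = diversity.aggregate_rank(
            default_study.table, default_study.taxonomy, "phylum"
        )
        fb = diversity.fb_ratio(abund).set_index("sample_id")
        meta = default_study.metadata.set_index("sample_id")
        wild = fb.loc[meta["status"] == "wild", "ratio"].median()
        ad = fb.loc[meta["status"] == "AD", "ratio"].median()
        assert ad < wild

    def test_age_taxa_correlate_with_age(self, default_study):
        truth = default_study.truth.taxa
        riser = truth.loc[truth["age_slope"] > 0, "taxon"]
        if len(riser) == 0:
            pytest.skip("no positive-slope age taxon drawn for this seed")
        rel = default_study.table.relative_abundance()
        ages = default_study.metadata.set_index("sample_id")["age"]
        from scipy.stats import spearmanr

        rhos = [
            spearmanr(rel.loc[t, ages.index], ages).statistic for t in riser
        ]
        assert np.mean(rhos) > 0.2

    def test_planted_taxon_reaches_all_eight_pools(self):
        """A planted strong shift is significant in every AD-vs-wild pool for
        nearly every planted genus (100 replicates of the benchmark)."""
        from wildgut import screen
        from wildgut.simulate import consensus_benchmark_config

        cfg = consensus_benchmark_config()
        in_all, total = 0, 0
        for rep in range(100):
            study = simulate_study(cfg, seed=7000 + rep)
            abund = diversity.aggregate_rank(study.table, study.taxonomy, "genus")
            pools = screen.build_pools(abund, study.metadata, reference="wild")
            for genus in study.truth.planted_genera():
                total += 1
                in_all += all(genus in p.taxa for p in pools)
        assert in_all / total >= 0.94

    def test_age_term_power_in_two_factor_permanova(self):
        """The planted age trend is detectable in beta diversity conditional
        on population in at least 90% of replicates."""
        from wildgut import host

        cfg = SimulationConfig()
        detections = 0
        for rep in range(50):
            study = simulate_study(cfg, seed=6000 + rep)
            dm = diversity.unifrac(study.table, study.tree, "weighted_normalized")
            res = host.trait_permanova(
                dm, study.metadata, "age", with_population=True,
                n_perm=199, seed=rep,
            )
            detections += res.term("age")["p_value"] < 0.05
        assert detections >= 45

    def test_age_screen_recovers_planted_genera(self):
        """Planted age-tracking genera pass the q < 0.1 screen."""
        from wildgut.host import age_screen

        cfg = SimulationConfig()
        recovered = total = 0
        for rep in range(20):
            study = simulate_study(cfg, seed=6100 + rep)
            genus = diversity.aggregate_rank(study.table, study.taxonomy, "genus")
            out = age_screen(genus, study.metadata).set_index("taxon")
            truth = study.truth.taxa
            for _, row in truth[truth["age_slope"] != 0].iterrows():
                total += 1
                g = row["genus"]
                recovered += g in out.index and out.loc[g, "q_value"] < 0.1
        assert recovered / total >= 0.85

    def test_heritability_shrinks_kin_distances(self, small_config):
        """With a strong heritable component, close kin are more similar."""
        cfg = SimulationConfig(
            populations=small_config.populations,
            taxa_per_phylum=small_config.taxa_per_phylum,
            heritability=0.8,
            n_heritable_taxa=20,
            population_effect_sd=0.0,
            depth_range=small_config.depth_range,
        )
        diffs = []
        for seed in range(6):
            study = simulate_study(cfg, seed=30 + seed)
            dm = diversity.unifrac(study.table, study.tree, "weighted_normalized")
            ped = PedigreeGraph(study.pedigree)
            meta = study.metadata.set_index("individual_id")
            caps = [i for i in meta.index if not meta.loc[i, "population"] == "wild"]
            close, far = [], []
            import itertools

            for a, b in itertools.combinations(caps, 2):
                k = ped.kinship_index(a, b)
                d = dm[meta.loc[a, "sample_id"], meta.loc[b, "sample_id"]]
                (close if k >= 0.5 else far if k == 0 else []).append(d)
            if close and far:
                diffs.append(np.mean(far) - np.mean(close))
        assert np.mean(diffs) > 0
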