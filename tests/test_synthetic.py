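"""Generator contracts: determinism, planted structure, recoverable effects."""

import numpy as np
import pytest
from scipy import stats

from rhizomics import synthetic as syn
from rhizomics.containers import cophenetic_matrix
from rhizomics.errors import InvalidArgumentError, InvalidDesignError, SchemaError


class TestPhylogeny:
    def test_minimal_tree_shape(self):
        tree = syn.generate_phylogeny(3, seed=1)
        tips = list(tree.tips())
        internal = [n for n in tree.traverse() if not n.is_tip()]
        assert len(tips) == 3
        assert len(internal) == 2  # root + one cherry ancestor

    def test_too_few_taxa_rejected(self):
        with pytest.raises(InvalidDesignError):
            syn.generate_phylogeny(2, seed=0)

    def test_newick_deterministic(self):
        a = str(syn.generate_phylogeny(100, seed=7))
        b = str(syn.generate_phylogeny(100, seed=7))
        assert a == b

    def test_cophenetic_is_metric(self):
        tree = syn.generate_phylogeny(50, seed=7)
        taxa = [t.name for t in tree.tips()]
        d = cophenetic_matrix(tree, taxa)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        # triangle inequality over all triples
        n = d.shape[0]
        for i in range(n):
            # vectorized check of d[i,j] <= d[i,k] + d[k,j] for all j,k
            assert np.all(d[i][None, :] <= d[i][:, None] + d + 1e-9)


class TestCommunities:
    def test_default_design_yields_full_grid(self):
        design = syn.StudyDesign(seed=1)
        matrix, metadata = syn.generate_communities(design, syn.default_truth(design))
        assert matrix.n_samples == 120
        assert len(metadata) == 120
        assert set(metadata["niche"]) == set(design.niches)

    def test_deterministic_given_seed(self, small_design, small_truth):
        m1, _ = syn.generate_communities(small_design, small_truth)
        m2, _ = syn.generate_communities(small_design, small_truth)
        assert m1.counts.equals(m2.counts)

    def test_no_empty_rows_or_columns(self, small_communities):
        matrix, _ = small_communities
        assert (matrix.counts.sum(axis=1) > 0).all()
        assert (matrix.counts.sum(axis=0) > 0).all()

    def test_richness_declines_along_continuum(self):
        """Mean observed richness strictly decreases across the four niches
        (averaged over 20 seeds) under declining retention."""
        niche_rich = {n: [] for n in syn.NICHE_ORDER}
        for seed in range(20):
            design = syn.StudyDesign(
                n_treatments=2, n_replicates=1, n_taxa=60, depth_mean=600, seed=seed
            )
            truth = syn.default_truth(design)
            truth = syn.PlantedTruth(
                biomarker_taxa=truth.biomarker_taxa,
                module_assignments=truth.module_assignments,
                niche_retention=(1.0, 0.6, 0.4, 0.2),
                cd_link=truth.cd_link,
            )
            matrix, meta = syn.generate_communities(design, truth)
            rich = (matrix.counts > 0).sum(axis=1)
            for niche in syn.NICHE_ORDER:
                ids = meta.loc[meta["niche"] == niche, "sample_id"]
                niche_rich[niche].append(rich.loc[ids].mean())
        means = [np.mean(niche_rich[n]) for n in syn.NICHE_ORDER]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_null_effects_give_no_cultivar_signal(self):
        """With zero effect sizes and full retention, planted taxa show a
        cultivar difference at alpha=0.05 in no more than ~10% of repeats."""
        n_repeats = 100
        sig = []
        for seed in range(n_repeats):
            design = syn.StudyDesign(
                n_treatments=2, n_replicates=2, niches=("bulk", "rhizosphere"),
                n_taxa=30, depth_mean=500, seed=seed,
            )
            truth = syn.default_truth(design, effect=0.0)
            truth = syn.PlantedTruth(
                biomarker_taxa=truth.biomarker_taxa,
                module_assignments=truth.module_assignments,
                niche_retention=(1.0, 1.0),
                cd_link={},
            )
            matrix, meta = syn.generate_communities(design, truth)
            rel = matrix.relative_abundance()
            cv = meta.set_index("sample_id")["cultivar"]
            taxon = sorted(truth.all_biomarkers())[seed % 5]
            if taxon not in rel.columns:
                continue
            a = rel.loc[cv == "XS14", taxon]
            b = rel.loc[cv == "YY17", taxon]
            sig.append(stats.ttest_ind(a, b).pvalue < 0.05)
        assert np.mean(sig) <= 0.12

    def test_planted_biomarkers_enriched(self, small_communities, small_truth):
        matrix, meta = small_communities
        rel = matrix.relative_abundance()
        cv = meta.set_index("sample_id")["cultivar"]
        for cultivar, taxa in small_truth.biomarker_taxa.items():
            other = [c for c in cv.unique() if c != cultivar][0]
            for taxon in taxa:
                enriched = rel.loc[cv == cultivar, taxon].mean()
                depleted = rel.loc[cv == other, taxon].mean()
                assert enriched > depleted

    def test_inconsistent_truth_rejected(self, small_design):
        truth = syn.PlantedTruth(
            biomarker_taxa={"XS14": {"NOT_A_TAXON": 2.0}},
            niche_retention=(1.0, 0.6, 0.4, 0.2),
        )
        with pytest.raises(SchemaError):
            syn.generate_communities(small_design, truth)


class TestAssemblyPairSet:
    def test_shape_and_determinism(self):
        m1, t1 = syn.generate_assembly_pair_set("drift", 50, seed=3)
        m2, _ = syn.generate_assembly_pair_set("drift", 50, seed=3)
        assert m1.n_samples == 100
        assert m1.counts.equals(m2.counts)
        assert len(syn.pair_index(m1)) == 50

    def test_unknown_scenario_rejected(self):
        with pytest.raises(InvalidArgumentError):
            syn.generate_assembly_pair_set("mystery", 5, seed=1)

    def test_selection_pairs_phylogenetically_clustered(self):
        """Within-community mean pairwise cophenetic distance under trait
        selection is below the pool average for same-size random draws."""
        matrix, tree = syn.generate_assembly_pair_set("selection", 5, seed=4)
        taxa = matrix.taxon_ids
        d = cophenetic_matrix(tree, taxa)
        rng = np.random.default_rng(0)
        for sid in matrix.sample_ids[:4]:
            present = np.flatnonzero(matrix.counts.loc[sid].to_numpy() > 0)
            sub = d[np.ix_(present, present)]
            observed = sub[np.triu_indices(len(present), 1)].mean()
            null = []
            for _ in range(999):
                pick = rng.choice(len(taxa), size=len(present), replace=False)
                nd = d[np.ix_(pick, pick)]
                null.append(nd[np.triu_indices(len(pick), 1)].mean())
            assert observed < np.mean(null)


class TestCdMeasurements:
    def _design(self, seed):
        return syn.StudyDesign(
            n_treatments=5, n_replicates=3, niches=("bulk", "rhizosphere"),
            n_taxa=40, depth_mean=500, seed=seed,
        )

    def test_outputs_positive(self, small_design, small_truth, small_communities):
        matrix, meta = small_communities
        cd = syn.generate_cd_measurements(small_design, small_truth, matrix, meta)
        for col in ("grain_cd", "soil_total_cd", "soil_available_cd"):
            assert (cd.table[col] > 0).all()

    def test_zero_link_gives_independence(self):
        """All-zero coefficients: the abundance-grain-Cd correlation behaves
        like a true null (significant in ~5% of repeats, mean r near 0)."""
        rs, sig = [], []
        for seed in range(60):
            design = self._design(seed)
            truth = syn.default_truth(design, cd_coefficient=0.0)
            matrix, meta = syn.generate_communities(design, truth)
            cd = syn.generate_cd_measurements(design, truth, matrix, meta)
            taxon = sorted(truth.cd_link)[0]
            rel = matrix.relative_abundance()
            ref = meta[meta["niche"] == "rhizosphere"]
            abund = rel.loc[ref["sample_id"], taxon].to_numpy()
            res = stats.pearsonr(abund, cd.table["grain_cd"])
            rs.append(res.statistic)
            sig.append(res.pvalue < 0.05)
        assert abs(np.mean(rs)) < 0.1
        assert np.mean(sig) <= 0.15

    def test_positive_link_detected(self):
        """A strong positive coefficient yields a significant positive
        Spearman correlation in >=90% of repeats."""
        hits = []
        for seed in range(30):
            design = self._design(seed + 500)
            truth = syn.default_truth(design, cd_coefficient=0.3)
            matrix, meta = syn.generate_communities(design, truth)
            cd = syn.generate_cd_measurements(design, truth, matrix, meta)
            taxon = sorted(truth.cd_link)[0]
            rel = matrix.relative_abundance()
            ref = meta[meta["niche"] == "rhizosphere"]
            abund = rel.loc[ref["sample_id"], taxon].to_numpy()
            res = stats.spearmanr(abund, cd.table["grain_cd"])
            hits.append(res.statistic > 0 and res.pvalue < 0.05)
        assert np.mean(hits) >= 0.9

    def test_missing_link_taxon_rejected(self, small_design, small_communities):
        matrix, meta = small_communities
        truth = syn.PlantedTruth(cd_link={"NOT_A_TAXON": 0.2}, niche_retention=(1, 1, 1, 1))
        with pytest.raises(SchemaError):
            syn.generate_cd_measurements(small_design, truth, matrix, meta)


class TestNestedNicheSet:
    def test_supports_are_nested(self):
        matrix, meta = syn.generate_nested_niche_set(seed=2)
        supports = {}
        for niche in syn.NICHE_ORDER:
            ids = meta.loc[meta["niche"] == niche, "sample_id"]
            supports[niche] = set(
                matrix.counts.columns[(matrix.counts.loc[ids] > 0).any(axis=0)]
            )
        order = list(syn.NICHE_ORDER)
        for up, down in zip(order, order[1:]):
            # downstream niches draw from a subset of the upstream profile;
            # a couple of rare taxa may be missed in the upstream samples
            assert len(supports[down] - supports[up]) <= 2
            assert len(supports[down]) < len(supports[up])
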