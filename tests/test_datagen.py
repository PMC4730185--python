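"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from mirnet import datagen
from mirnet.clinical import kruskal_wallis
from mirnet.correlate import spearman_rho
from mirnet.datagen import CohortConfig
from mirnet.io_core import ValidationError


class TestGenerateCohort:
    def test_identical_seed_gives_identical_output(self, small_config):
        a = datagen.generate_cohort(small_config)
        b = datagen.generate_cohort(small_config)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        assert a[3].regulators == b[3].regulators

    def test_infeasible_target_count_rejected(self):
        with pytest.raises(ValidationError, match="exceed"):
            CohortConfig(n_gene=10, n_regulators=3, targets_per_regulator=5)

    def test_no_regulators_means_no_planted_shift(self):
        cfg = CohortConfig(n_patients=400, n_mirna=40, n_gene=20,
                           n_regulators=0, n_de_decoys=0, batch_shift_sd=0.0,
                           seed=5)
        mir, _, design, truth = datagen.generate_cohort(cfg)
        assert truth.regulators == []
        tumor = mir.data[[design.tumor_col[p] for p in design.patient_ids]]
        adj = mir.data[[design.adjacent_col[p] for p in design.patient_ids]]
        log2fc = (tumor.to_numpy() - adj.to_numpy()).mean(axis=1)
        assert np.abs(log2fc).mean() < 0.1  # -> 0 as n grows

    def test_regulator_target_spearman_negative(self):
        """Median rho between each regulator and its targets < -0.3 at c=0.5,
        cross-checked against direct rho computation on the generated matrix."""
        cfg = CohortConfig(n_patients=100, n_mirna=30, n_gene=300,
                           n_regulators=2, targets_per_regulator=30,
                           coupling_strength=0.5, seed=17)
        mir, mrna, design, truth = datagen.generate_cohort(cfg)
        for reg in truth.regulators:
            x = mir.data.loc[reg.mirna_id].to_numpy()
            rhos = [spearman_rho(x, mrna.data.loc[t].to_numpy())
                    for t in reg.targets]
            assert np.median(rhos) < -0.3

    def test_matrix_column_layout_matches_design(self, small_cohort):
        mir, mrna, design, _ = small_cohort
        assert mir.shape[1] == 2 * len(design.patient_ids)
        design.validate_against(mir)
        design.validate_against(mrna)
        for p in design.patient_ids:  # both tissues share the batch
            assert (design.batch[design.tumor_col[p]]
                    == design.batch[design.adjacent_col[p]])

    def test_nonregulator_rho_symmetric_about_zero(self, small_cohort):
        mir, mrna, _, truth = small_cohort
        planted_m = set(truth.regulator_ids) | set(truth.decoy_de)
        planted_g = {t for r in truth.regulators for t in r.targets}
        rng = np.random.default_rng(0)
        free_m = [m for m in mir.feature_ids if m not in planted_m]
        free_g = [g for g in mrna.feature_ids if g not in planted_g]
        rhos = [
            spearman_rho(mir.data.loc[rng.choice(free_m)].to_numpy(),
                         mrna.data.loc[rng.choice(free_g)].to_numpy())
            for _ in range(300)
        ]
        signs = np.sign(rhos)
        p = stats.binomtest(int((signs > 0).sum()), len(signs)).pvalue
        assert p > 0.01

    def test_planted_regulators_pass_de_filter_with_stated_power(self):
        """At log2(1.8) shift, noise 1, n=100, each planted regulator passes
        |FC|>1.5 & FDR<0.05 in >= 95% of replicate cohorts."""
        from mirnet.diffexpr import de_analysis

        n_rep, hits, total = 50, 0, 0
        for rep in range(n_rep):
            cfg = CohortConfig(n_patients=100, n_mirna=60, n_gene=10,
                               n_regulators=2, targets_per_regulator=5,
                               regulator_log2fc=float(np.log2(1.8)),
                               noise_sd=1.0, n_de_decoys=0, seed=9000 + rep)
            mir, _, design, truth = datagen.generate_cohort(cfg)
            de = de_analysis(mir, design)
            de_ids = set(de.index[de["is_de"]])
            hits += len(set(truth.regulator_ids) & de_ids)
            total += len(truth.regulator_ids)
        assert hits / total >= 0.95


class TestGeneratePredictions:
    def test_perfect_sensitivity_no_fp_equals_truth(self, small_cohort):
        truth = small_cohort[3]
        pred = datagen.generate_predictions(truth, "P", sensitivity=1.0,
                                            fp_per_mirna=0, seed=1)
        for reg in truth.regulators:
            assert set(pred.targets_of(reg.mirna_id)["gene_id"]) == set(reg.targets)

    def test_zero_sensitivity_no_fp_empty(self, small_cohort):
        truth = small_cohort[3]
        pred = datagen.generate_predictions(truth, "P", sensitivity=0.0,
                                            fp_per_mirna=0, seed=1)
        assert len(pred.table) == 0

    def test_inclusion_count_within_binomial_interval(self):
        cfg = CohortConfig(n_patients=4, n_mirna=30, n_gene=1500,
                           n_regulators=20, targets_per_regulator=50,
                           n_de_decoys=0, seed=3)
        truth = datagen.generate_cohort(cfg)[3]
        pred = datagen.generate_predictions(truth, "P", sensitivity=0.8,
                                            fp_per_mirna=0, seed=77)
        included = len(pred.table)  # 1000 true targets at sensitivity 0.8
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.8)
        assert lo <= included <= hi

    def test_true_targets_score_higher_on_average(self, small_cohort):
        truth = small_cohort[3]
        pred = datagen.generate_predictions(truth, "P", sensitivity=1.0,
                                            fp_per_mirna=20, seed=4)
        reg = truth.regulators[0]
        sub = pred.targets_of(reg.mirna_id)
        is_true = sub["gene_id"].isin(reg.targets)
        assert sub[is_true]["score"].mean() > sub[~is_true]["score"].mean()

    def test_deterministic_under_seed(self, small_cohort):
        truth = small_cohort[3]
        a = datagen.generate_predictions(truth, "P", seed=12)
        b = datagen.generate_predictions(truth, "P", seed=12)
        assert a.table.equals(b.table)


class TestGeneratePathwayDb:
    def test_no_decoys_gives_exactly_planted(self, small_cohort):
        truth = small_cohort[3]
        coll, hier = datagen.generate_pathway_db(truth, n_decoy_sets=0, seed=8)
        assert set(coll.sets) == set(truth.planted_pathways)

    def test_every_pathway_once_in_hierarchy(self, small_cohort):
        truth = small_cohort[3]
        coll, hier = datagen.generate_pathway_db(truth, n_decoy_sets=10, seed=8)
        assert sorted(hier.table["pathway_id"]) == sorted(coll.sets)
        assert not hier.table["pathway_id"].duplicated().any()

    def test_planted_pathways_span_multiple_groups(self, small_cohort):
        truth = small_cohort[3]
        _, hier = datagen.generate_pathway_db(truth, n_decoy_sets=0, seed=8)
        assert hier.table["group_id"].nunique() >= 2

    def test_decoy_overlap_matches_hypergeometric_expectation(self, small_cohort):
        """Mean overlap of uniform decoy sets with a planted set ~ k*m/n_gene."""
        truth = small_cohort[3]
        planted_id, planted = next(iter(truth.planted_pathways.items()))
        m, n_gene = len(planted), truth.config.n_gene
        k_lo = k_hi = 24
        overlaps = []
        for rep in range(200):
            coll, _ = datagen.generate_pathway_db(
                truth, n_decoy_sets=5, set_size_range=(k_lo, k_hi), seed=rep)
            overlaps += [
                len(set(coll.sets[s]) & set(planted))
                for s in coll.sets if s.startswith("decoy")
            ]
        expected = k_lo * m / n_gene
        se = np.sqrt(expected / len(overlaps))  # ~Poisson spread
        assert abs(np.mean(overlaps) - expected) < 5 * se + 0.05


class TestGenerateClinical:
    def test_row_count_and_levels(self, small_cohort):
        mir, _, design, truth = small_cohort
        tab = datagen.generate_clinical(truth, design, seed=6).table
        assert len(tab) == truth.config.n_patients
        from mirnet.io_core import CLINICAL_LEVELS
        for col, levels in CLINICAL_LEVELS.items():
            observed = set(tab[col].dropna())
            assert observed <= set(levels)

    def test_deterministic_under_seed(self, small_cohort):
        _, _, design, truth = small_cohort
        a = datagen.generate_clinical(truth, design, seed=6).table
        b = datagen.generate_clinical(truth, design, seed=6).table
        assert a.equals(b)

    def test_assoc_requires_matrix(self, small_cohort):
        _, _, design, truth = small_cohort
        with pytest.raises(ValidationError, match="matrix"):
            datagen.generate_clinical(truth, design,
                                      assoc_mirna=truth.regulator_ids[0], seed=6)

    def test_null_kruskal_p_uniform(self, small_cohort):
        """Without a planted association, miRNA-vs-covariate Kruskal-Wallis
        p-values are uniform: fraction < 0.05 stays near 0.05."""
        mir, _, design, truth = small_cohort
        mirna_id = truth.regulator_ids[0]
        tumor = mir.data.loc[mirna_id,
                             [design.tumor_col[p] for p in design.patient_ids]]
        flags, total = 0, 0
        for rep in range(500):
            tab = datagen.generate_clinical(truth, design, seed=10_000 + rep).table
            _, p = kruskal_wallis(tumor.to_numpy(), tab["stage"].to_numpy())
            flags += p < 0.05
            total += 1
        rate = flags / total
        assert abs(rate - 0.05) < 0.035  # ~4 sigma of binomial(500, .05)
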