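import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from candgene.association import (
    AssociationError,
    GeneActionRecord,
    association_scan,
    gene_action,
    gene_action_from_data,
    gene_action_from_effects,
    mendelian_test,
    ritland_kinship,
    single_marker_anova,
    storey_qvalues,
    validate_panel,
)
from candgene.datasets import PTUXS1_MARKER_EFFECTS
from candgene.genotypes import GenotypeMatrix
from candgene.simulate import (
    QTLSpec,
    SimulationConfig,
    simulate_phenotypes,
    simulate_structured_population,
)


def geno(dosages):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(d, [f"i{k}" for k in range(d.shape[0])],
                          [f"SNP{k + 1}" for k in range(d.shape[1])])


class TestRitlandKinship:
    def test_unrelated_panmictic_mean_near_zero(self, rng):
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 800), size=(100, 800))
        K = ritland_kinship(geno(g))
        off = K[~np.eye(100, dtype=bool)]
        # truncation at zero biases the mean up slightly; stays small
        assert off.mean() < 0.02
        assert (np.diag(K) == 1.0).all()

    def test_duplicated_individual_high_estimate(self, rng):
        g = rng.binomial(2, 0.5, size=(50, 300)).astype(float)
        g[1] = g[0]
        K = ritland_kinship(geno(g))
        assert K[0, 1] >= 0.9

    def test_full_sibs_rank_above_unrelated(self):
        hits = 0
        for seed in range(10):
            config = SimulationConfig(
                seed=seed, n_individuals=60, n_snps=60, n_families=10,
                family_size=2, qtl_effects=())
            gm, _, K_true = simulate_structured_population(config)
            K = ritland_kinship(gm)
            sib_mask = (K_true == 0.5)
            unrel_mask = (K_true == 0.0)
            if K[sib_mask].mean() > K[unrel_mask].mean():
                hits += 1
        assert hits >= 9

    def test_all_monomorphic_raises(self):
        with pytest.raises(AssociationError):
            ritland_kinship(geno(np.zeros((10, 5))))


class TestStoreyQvalues:
    def test_pi0_one_equals_bh_stepup(self, rng):
        """With π0 forced to 1 the q-values equal BH adjusted p-values."""
        for _ in range(10):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(5, 200)))
            q = storey_qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh, atol=1e-12)

    def test_worked_example(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_identical_ps_identical_qs(self):
        q = storey_qvalues([0.2] * 6)
        assert len(set(np.round(q, 12))) == 1

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 100) + 1e-9
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(AssociationError):
            storey_qvalues([0.5, 0.0])
        with pytest.raises(AssociationError):
            storey_qvalues([0.5, 1.2])


class TestGeneAction:
    def test_midpoint_heterozygote_is_additive(self):
        rec = gene_action(g_BB=10, g_Bb=9, g_bb=8, minor_freq=0.3,
                          trait_sd=1.0, overall_mean=9.0)
        assert rec.two_a == 2 and rec.d == 0 and rec.d_over_a == 0
        assert rec.mode == "additive"

    @pytest.mark.parametrize("two_a,d,expected_ratio,expected_mode", [
        (1.3871, 0.3247, 0.4682, "additive"),       # α-cellulose / SNP10
        (1.6288, 0.8427, 1.0347, "dominant"),       # microfibril angle / SNP68
        (1.7470, 3.2853, 3.7611, "overdominant"),   # holocellulose / SNP22
    ])
    def test_published_effect_rows(self, two_a, d, expected_ratio,
                                   expected_mode):
        ratio, mode = gene_action_from_effects(two_a, d)
        assert round(ratio, 4) == expected_ratio
        assert mode == expected_mode

    def test_published_table_classification_counts(self):
        modes = [gene_action_from_effects(r.two_a, r.d)[1]
                 for r in PTUXS1_MARKER_EFFECTS.itertuples()]
        assert modes.count("additive") == 2
        assert modes.count("dominant") == 6
        assert modes.count("overdominant") == 1

    def test_boundary_half_is_additive(self):
        # planted a=0.7, d=0.35 → |d/a| = 0.5 exactly → additive
        ratio, mode = gene_action_from_effects(1.4, 0.35)
        assert ratio == pytest.approx(0.5)
        assert mode == "additive"

    def test_boundary_125_is_overdominant(self):
        _, mode = gene_action_from_effects(2.0, 1.25)
        assert mode == "overdominant"

    def test_missing_class_returns_none(self):
        y = np.arange(10, dtype=float)
        marker = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        with pytest.warns(UserWarning):
            assert gene_action_from_data(y, marker) is None


class TestMendelian:
    def test_perfect_ratio(self):
        progeny = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        chi2, p, keep = mendelian_test(progeny, 1, 1)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert keep

    def test_worked_example_aa_x_AA(self):
        # Aa × AA with counts (40, 60): χ² = (40−50)²/50 + (60−50)²/50 = 4.0
        progeny = np.repeat([1.0, 2.0], [40, 60])
        chi2, p, keep = mendelian_test(progeny, 1, 2)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=0.0005)
        assert keep

    def test_monomorphic_cross_skipped(self):
        with pytest.raises(AssociationError):
            mendelian_test(np.zeros(100), 0, 0)

    def test_size_about_one_percent(self, rng):
        rejections = 0
        trials = 400
        for _ in range(trials):
            gam1 = rng.integers(0, 2, 500)
            gam2 = rng.integers(0, 2, 500)
            _, _, keep = mendelian_test((gam1 + gam2).astype(float), 1, 1)
            rejections += not keep
        se = np.sqrt(0.01 * 0.99 / trials)
        assert rejections / trials <= 0.01 + 3 * se


class TestAnova:
    def test_matches_scipy_oneway(self, rng):
        y = rng.standard_normal(90)
        g = rng.integers(0, 3, 90).astype(float)
        p, r2 = single_marker_anova(y, g)
        groups = [y[g == c] for c in np.unique(g)]
        assert p == pytest.approx(stats.f_oneway(*groups).pvalue, abs=1e-12)
        assert 0 <= r2 <= 100

    def test_identical_means_large_n(self, rng):
        g = np.tile([0.0, 1.0, 2.0], 400)
        y = np.tile(rng.standard_normal(400), 3)  # same data in each class
        p, r2 = single_marker_anova(y, g)
        assert p > 0.99
        assert r2 < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(AssociationError):
            single_marker_anova(np.arange(5, dtype=float), np.ones(5))


class TestScan:
    def test_planted_qtl_flagged_and_duplicate_equal_p(self, small_study):
        gm = small_study["genotypes"]
        ph = small_study["phenotypes"]
        # duplicate the first planted QTL's SNP
        truth = small_study["truth"].iloc[0]
        j = int(truth.snp_index)
        dup = GenotypeMatrix(
            np.hstack([gm.dosages, gm.dosages[:, [j]]]),
            list(gm.individuals), gm.snp_ids + ["SNPdup"],
            np.append(gm.positions, gm.positions[j]),
        )
        res = association_scan(dup, ph, Q=small_study["Q"],
                               K=small_study["K"])
        sig = res[res.significant]
        assert ((sig.snp_id == truth.snp_id)
                & (sig.trait == truth.trait)).any()
        sub = res[res.trait == truth.trait].set_index("snp_id")
        assert sub.loc["SNPdup", "p_value"] == \
            pytest.approx(sub.loc[truth.snp_id, "p_value"], abs=1e-9)

    def test_id_mismatch_raises(self, small_study):
        gm = small_study["genotypes"]
        ph = small_study["phenotypes"].rename(index={"ind1": "stranger"})
        with pytest.raises(AssociationError, match="missing"):
            association_scan(gm, ph)


class TestValidatePanel:
    def test_progeny_panel_confirms_planted_effect(self, small_study):
        progeny = small_study["progeny"]
        res = validate_panel(
            progeny, small_study["parent1"], small_study["parent2"],
            small_study["progeny_phenotypes"],
        )
        assert not res.empty
        # almost all truly Mendelian loci pass the χ² screen
        kept = res.drop_duplicates("snp_id")["keep"]
        assert kept.mean() >= 0.9
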