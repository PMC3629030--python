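import numpy as np
import pytest

from candgene.association import gene_action_from_data
from candgene.diversity import segregating_sites
from candgene.genemodel import gene_model_from_lengths
from candgene.simulate import (
    QTLSpec,
    SimulationConfig,
    SimulationError,
    genotypes_from_haplotypes,
    simulate_f1_cross,
    simulate_haplotype_alignment,
    simulate_phenotypes,
    simulate_structured_population,
    simulate_study,
)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=5, n_individuals=60, n_snps=20,
                               n_progeny=50, qtl_effects=(QTLSpec(3, 0, 0.5),))
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert (a["alignment"].matrix == b["alignment"].matrix).all()
        assert np.array_equal(a["genotypes"].dosages, b["genotypes"].dosages)
        assert a["phenotypes"].equals(b["phenotypes"])
        assert np.array_equal(a["progeny"].dosages, b["progeny"].dosages)

    def test_different_seeds_differ(self):
        a = simulate_haplotype_alignment(SimulationConfig(seed=1))
        b = simulate_haplotype_alignment(SimulationConfig(seed=2))
        assert (a.matrix != b.matrix).any()


class TestAlignment:
    def test_zero_mutation_rate_gives_no_segregating_sites(self):
        aln = simulate_haplotype_alignment(
            SimulationConfig(seed=9, theta_per_site=0.0))
        assert segregating_sites(aln) == 0

    def test_observed_s_within_its_own_sampling_distribution(self):
        """S for one seed lies inside the central 99% of the simulator's own
        S distribution (estimated by repeated simulation)."""
        model = gene_model_from_lengths([("five_prime_utr", 1000)])
        dist = []
        for seed in range(300):
            cfg = SimulationConfig(seed=1000 + seed, n_haplotypes=2,
                                   theta_per_site=0.01, gene_model=model)
            dist.append(segregating_sites(simulate_haplotype_alignment(cfg)))
        observed = dist[0]
        lo, hi = np.quantile(dist, [0.005, 0.995])
        assert lo <= observed <= hi

    def test_variant_columns_partition_into_regions(self):
        cfg = SimulationConfig(seed=3, n_haplotypes=20)
        aln = simulate_haplotype_alignment(cfg)
        model = cfg.gene_model
        n_all = aln.n_alleles()
        for j in np.flatnonzero(n_all >= 2):
            model.assign_region(int(j))  # raises if not in exactly one region

    def test_gap_injection(self):
        aln = simulate_haplotype_alignment(
            SimulationConfig(seed=4, gap_columns=25))
        assert aln.has_gap().sum() == 25

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(theta_per_site=-1)
        with pytest.raises(SimulationError):
            SimulationConfig(subpop_proportions=(0.5, 0.4))
        with pytest.raises(SimulationError):
            SimulationConfig(maf_min=0.6)


class TestStructuredPopulation:
    def test_maf_floor_holds_for_every_snp(self):
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, n_individuals=200, n_snps=40,
                                   qtl_effects=())
            gm, _, _ = simulate_structured_population(cfg)
            assert (gm.maf() >= cfg.maf_min).all()

    def test_q_matrix_bookkeeping(self):
        cfg = SimulationConfig(seed=8, subpop_proportions=(0.42, 0.20, 0.38),
                               qtl_effects=())
        gm, Q, _ = simulate_structured_population(cfg)
        assert Q.shape == (426, 3)
        assert (Q.sum(axis=1) == 1.0).all()
        # largest-remainder allocation of 426 individuals
        assert Q.sum(axis=0).sum() == 426
        assert np.array_equal(Q.sum(axis=0), [179, 85, 162])

    def test_identity_kinship_without_families(self):
        cfg = SimulationConfig(seed=2, n_individuals=50, n_snps=10,
                               qtl_effects=())
        _, _, K = simulate_structured_population(cfg)
        assert np.array_equal(K, np.eye(50))

    def test_ld_decreases_with_distance(self):
        from candgene.ld import pairwise_r2
        cfg = SimulationConfig(seed=6, n_individuals=300, n_snps=30,
                               fst=0.0, subpop_proportions=(1.0,),
                               ld_decay_scale=500.0, qtl_effects=())
        gm, _, _ = simulate_structured_population(cfg)
        _, pairs = pairwise_r2(gm)
        near = pairs[pairs.distance_bp < 300].r2.mean()
        far = pairs[pairs.distance_bp > 2000].r2.mean()
        assert near > far


class TestPhenotypes:
    def test_pure_noise_variance(self):
        cfg = SimulationConfig(seed=3, n_individuals=426, n_snps=10,
                               qtl_effects=())
        gm, _, K = simulate_structured_population(cfg)
        ph = simulate_phenotypes(gm, K, [], h2_polygenic=0.0, noise_sd=1.0,
                                 seed=1, n_traits=10)
        variances = ph.to_numpy().var(axis=0, ddof=1)
        assert variances.mean() == pytest.approx(1.0, rel=0.10)

    def test_pure_additive_qtl_has_zero_dominance(self):
        cfg = SimulationConfig(seed=3, n_individuals=200, n_snps=10,
                               qtl_effects=())
        gm, _, _ = simulate_structured_population(cfg)
        ph = simulate_phenotypes(gm, None, [QTLSpec(2, 0, 0.8, 0.0)],
                                 h2_polygenic=0.0, noise_sd=0.0, seed=1,
                                 n_traits=1)
        y = ph["trait_1"].to_numpy()
        g = gm.dosages[:, 2]
        d = y[g == 1].mean() - 0.5 * (y[g == 2].mean() + y[g == 0].mean())
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_boundary_d_over_a_classified_additive(self):
        """Planted a=0.7, d=0.35 (d/a = 0.5) sits exactly on the additive/
        dominant boundary and is classified additive."""
        cfg = SimulationConfig(seed=3, n_individuals=200, n_snps=10,
                               qtl_effects=())
        gm, _, _ = simulate_structured_population(cfg)
        ph = simulate_phenotypes(gm, None, [QTLSpec(2, 0, 0.7, 0.35)],
                                 h2_polygenic=0.0, noise_sd=0.0, seed=1,
                                 n_traits=1)
        rec = gene_action_from_data(ph["trait_1"].to_numpy(),
                                    gm.dosages[:, 2])
        assert abs(rec.d_over_a) == pytest.approx(0.5, abs=1e-9)
        assert rec.mode == "additive"

    def test_non_psd_kinship_rejected(self):
        cfg = SimulationConfig(seed=3, n_individuals=20, n_snps=5,
                               qtl_effects=())
        gm, _, _ = simulate_structured_population(cfg)
        with pytest.raises(SimulationError, match="PSD"):
            simulate_phenotypes(gm, -np.eye(20), [], 0.5, 1.0, seed=1)


class TestF1Cross:
    def test_homozygous_parents_monomorphic_progeny(self):
        prog = simulate_f1_cross(np.array([2.0]), np.array([2.0]), 100, seed=1)
        assert (prog.dosages == 2.0).all()

    def test_het_by_hom_cross_classes(self):
        prog = simulate_f1_cross(np.array([1.0]), np.array([2.0]), 500, seed=2)
        assert set(np.unique(prog.dosages)) == {1.0, 2.0}

    def test_het_cross_segregates_one_two_one(self):
        """Aa × Aa at n = 4000: class proportions within 3 binomial SEs
        of 1:2:1."""
        n = 4000
        prog = simulate_f1_cross(np.array([1.0]), np.array([1.0]), n, seed=3)
        counts = np.array([(prog.dosages == c).sum() for c in (0.0, 1.0, 2.0)])
        expected = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(counts / n - expected) <= 3 * se).all()

    def test_missing_parent_locus_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            prog = simulate_f1_cross(np.array([1.0, np.nan]),
                                     np.array([1.0, 2.0]), 10, seed=4)
        assert prog.n_snps == 1


class TestEndToEndCoupling:
    def test_genotypes_from_haplotypes_respects_maf(self):
        aln = simulate_haplotype_alignment(SimulationConfig(seed=12))
        gm = genotypes_from_haplotypes(aln, maf_min=0.10, seed=1)
        assert gm.n_individuals == 44
        assert (gm.maf() > 0).all()
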