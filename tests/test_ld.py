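import numpy as np
import pytest

from candgene.genotypes import GenotypeMatrix
from candgene.ld import (
    DecayFit,
    HaplotypeBlock,
    LDError,
    detect_blocks,
    em_two_locus_frequencies,
    fit_ld_decay,
    hill_weir_expected_r2,
    pairwise_r2,
    r2_significance,
)


def geno(dosages, positions=None):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        d, [f"i{k}" for k in range(d.shape[0])],
        [f"SNP{k + 1}" for k in range(d.shape[1])],
        positions,
    )


def haplotype_counting_oracle(haps1, haps2):
    """Direct haplotype frequency counting from phased truth."""
    pairs = list(zip(haps1, haps2))
    n = len(pairs)
    return {h: pairs.count(h) / n for h in {(a, b) for a in (0, 1) for b in (0, 1)}}


class TestTwoLocusEM:
    def test_unambiguous_homozygotes(self):
        g = np.array([[2, 2]] * 50 + [[0, 0]] * 50, dtype=float)
        f = em_two_locus_frequencies(g[:, 0], g[:, 1])
        assert f.p_AB == pytest.approx(0.5, abs=1e-9)
        assert f.p_ab == pytest.approx(0.5, abs=1e-9)
        assert f.p_Ab == pytest.approx(0.0, abs=1e-9)
        assert f.r2 == pytest.approx(1.0, abs=1e-9)

    def test_all_double_heterozygotes_tie_break(self):
        """Coupling/repulsion are equally likely; the D ≥ 0 solution wins."""
        g = np.array([[1, 1]] * 40, dtype=float)
        f = em_two_locus_frequencies(g[:, 0], g[:, 1])
        assert f.D >= 0
        assert f.r2 == pytest.approx(1.0, abs=1e-6)

    def test_matches_counting_oracle_on_phased_truth(self, rng):
        """Frequencies within 1e-6 of direct counting when phase is
        unambiguous (one locus homozygous in every individual)."""
        n = 200
        h1a = rng.integers(0, 2, n)
        h1b = h1a.copy()                      # locus 1 homozygous everywhere
        h2a = (h1a + rng.integers(0, 2, n)) % 2
        h2b = (h1b + rng.integers(0, 2, n)) % 2
        g1 = (h1a + h1b).astype(float)
        g2 = (h2a + h2b).astype(float)
        f = em_two_locus_frequencies(g1, g2)
        truth = haplotype_counting_oracle(
            np.concatenate([h1a, h1b]), np.concatenate([h2a, h2b]))
        assert f.p_AB == pytest.approx(truth[(1, 1)], abs=1e-6)
        assert f.p_ab == pytest.approx(truth[(0, 0)], abs=1e-6)

    def test_em_loglik_monotone(self, rng):
        for _ in range(10):
            g1 = rng.integers(0, 3, 80).astype(float)
            g2 = rng.integers(0, 3, 80).astype(float)
            try:
                f = em_two_locus_frequencies(g1, g2, track=True)
            except LDError:
                continue
            trace = np.array(f.ll_trace)
            assert (np.diff(trace) >= -1e-9).all()

    def test_monomorphic_locus_flagged(self):
        with pytest.raises(LDError):
            em_two_locus_frequencies(np.zeros(50), np.ones(50))


class TestPairwiseR2:
    def test_duplicated_locus(self, rng):
        g = rng.integers(0, 3, size=(100, 1)).astype(float)
        gm = geno(np.hstack([g, g]))
        r2, pairs = pairwise_r2(gm)
        assert r2[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diag(r2) == 1.0).all()

    def test_independent_loci_near_zero(self, rng):
        g = rng.binomial(2, 0.4, size=(10000, 2)).astype(float)
        r2, _ = pairwise_r2(geno(g))
        assert r2[0, 1] < 0.01  # E[r²] ≈ 1/n under independence

    def test_symmetric_and_matches_per_pair(self, rng):
        g = rng.binomial(2, 0.5, size=(120, 3)).astype(float)
        r2, pairs = pairwise_r2(geno(g))
        assert np.allclose(r2, r2.T, equal_nan=True)
        for _, row in pairs.iterrows():
            f = em_two_locus_frequencies(g[:, row.i], g[:, row.j])
            assert row.r2 == pytest.approx(f.r2, abs=1e-12)


class TestPermutationSignificance:
    def test_duplicated_locus_minimal_p(self, rng):
        g = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        gm = geno(np.hstack([g, g]))
        p = r2_significance(gm, 0, 1, n_permutations=199, seed=1)
        assert p <= 0.05

    def test_independence_table_gives_p_one(self):
        """A perfectly balanced joint table has r² = 0 exactly, so every
        permutation matches or beats it."""
        g1 = np.repeat([0, 1, 2], 9).astype(float)
        g2 = np.tile([0, 1, 2], 9).astype(float)
        gm = geno(np.column_stack([g1, g2]))
        f = em_two_locus_frequencies(g1, g2)
        assert f.r2 == pytest.approx(0.0, abs=1e-12)
        p = r2_significance(gm, 0, 1, n_permutations=199, seed=2)
        assert p == 1.0


class TestDecayFit:
    def test_ols_slope_negative_on_decaying_panel(self, small_study):
        gm = small_study["genotypes"]
        _, pairs = pairwise_r2(gm)
        fit = fit_ld_decay(pairs, n_sequences=2 * gm.n_individuals)
        assert fit.ols_slope < 0

    def test_constant_r2_has_no_crossing(self):
        import pandas as pd
        pairs = pd.DataFrame({
            "distance_bp": np.arange(1, 50, dtype=float),
            "r2": np.ones(49),
        })
        fit = fit_ld_decay(pairs, n_sequences=100)
        assert fit.distance_at_r2(0.1, model="hill_weir") is None

    def test_hill_weir_curve_monotone_decreasing(self):
        d = np.linspace(0, 5000, 200)
        vals = hill_weir_expected_r2(1e-3 * d, 852)
        assert (np.diff(vals) < 0).all()

    def test_identical_distances_rejected(self):
        import pandas as pd
        pairs = pd.DataFrame({"distance_bp": [5.0] * 10, "r2": [0.5] * 10})
        with pytest.raises(LDError):
            fit_ld_decay(pairs, n_sequences=100)


class TestBlockDetection:
    def test_perfect_block_detected(self):
        m = 10
        r2 = np.full((m, m), 0.05)
        np.fill_diagonal(r2, 1.0)
        for i in range(2, 6):
            for j in range(2, 6):
                r2[i, j] = 0.9
        blocks = detect_blocks(r2, threshold=0.75)
        assert [(b.start_snp_index, b.end_snp_index) for b in blocks] == [(2, 5)]

    def test_independent_snps_no_blocks(self):
        r2 = np.full((8, 8), 0.1)
        np.fill_diagonal(r2, 1.0)
        assert detect_blocks(r2) == []

    def test_invariant_to_values_above_threshold(self, rng):
        """Only the > threshold predicate matters, not the r² magnitudes."""
        m = 12
        base = np.full((m, m), 0.2)
        np.fill_diagonal(base, 1.0)
        for i in range(4, 8):
            for j in range(4, 8):
                base[i, j] = max(base[i, j], 0.76)
        jitter = base.copy()
        above = base > 0.75
        jitter[above] = rng.uniform(0.751, 1.0, size=above.sum())
        np.fill_diagonal(jitter, 1.0)
        assert detect_blocks(base) == detect_blocks(jitter)

    def test_p_value_gate(self):
        m = 4
        r2 = np.full((m, m), 0.9)
        p = np.full((m, m), 0.5)   # never significant
        assert detect_blocks(r2, p_matrix=p) == []
        assert detect_blocks(r2, p_matrix=np.full((m, m), 1e-5)) \
            == [HaplotypeBlock(0, 3)]
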