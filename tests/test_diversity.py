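import itertools

import numpy as np
import pytest

from candgene.alignment import AlignmentSet
from candgene.annotation import classify_alignment_sites
from candgene.diversity import (
    DiversityError,
    diversity_table,
    diversity_totals,
    harmonic_number,
    nucleotide_diversity_pi,
    percent_polymorphism,
    segregating_sites,
    snp_frequency,
    watterson_theta,
)
from candgene.simulate import SimulationConfig, simulate_haplotype_alignment


def make_alignment(rows):
    return AlignmentSet([f"s{i}" for i in range(len(rows))],
                        np.array([list(r) for r in rows], dtype="S1"))


def brute_force_pi(aln: AlignmentSet) -> float:
    """O(n²L) oracle: mean pairwise difference proportion over usable columns."""
    usable = [
        j for j in range(aln.length)
        if b"-" not in aln.matrix[:, j].tobytes()
        and len(set(aln.matrix[:, j].tobytes())) <= 2
    ]
    pairs = list(itertools.combinations(range(aln.n_sequences), 2))
    total = sum(
        int(aln.matrix[i, j] != aln.matrix[k, j])
        for (i, k) in pairs for j in usable
    )
    return total / (len(pairs) * len(usable))


class TestBasics:
    def test_identical_sequences(self):
        aln = make_alignment(["ACGTACGTAC"] * 4)
        assert segregating_sites(aln) == 0
        assert nucleotide_diversity_pi(aln) == 0.0
        assert watterson_theta(aln) == 0.0

    def test_two_sequences_one_mismatch(self):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAT"])
        assert segregating_sites(aln) == 1
        assert nucleotide_diversity_pi(aln) == pytest.approx(0.1)
        # a_1 = 1, so theta_w = S/L = 0.1
        assert watterson_theta(aln) == pytest.approx(0.1)

    def test_watterson_harmonic_scaling(self):
        # n=5, S=7, L=100: theta = 7 / (a_4 * 100), a_4 = 1+1/2+1/3+1/4
        base = "A" * 100
        rows = [list(base) for _ in range(5)]
        for j in range(7):
            rows[1 + j % 4][j] = "T"
        aln = make_alignment(["".join(r) for r in rows])
        assert segregating_sites(aln) == 7
        a4 = 1 + 1 / 2 + 1 / 3 + 1 / 4
        assert watterson_theta(aln) == pytest.approx(7 / (a4 * 100))
        assert harmonic_number(4) == pytest.approx(a4)

    def test_single_sequence_raises(self):
        with pytest.raises(DiversityError):
            segregating_sites(make_alignment(["ACGT"]))


class TestOracleEquivalence:
    def test_pi_matches_pairwise_enumeration(self, rng):
        """π equals the brute-force O(n²L) pairwise oracle on random data."""
        for _ in range(5):
            mat = rng.choice(list("ACGT"), size=(6, 50))
            # plant some shared variation
            mat[:3, 7] = "A"; mat[3:, 7] = "G"
            aln = AlignmentSet([f"s{i}" for i in range(6)],
                               mat.astype("S1"))
            assert nucleotide_diversity_pi(aln) == \
                pytest.approx(brute_force_pi(aln), abs=1e-12)

    def test_gap_exclusion_never_increases_s(self, rng):
        config = SimulationConfig(seed=77, n_haplotypes=10)
        clean = simulate_haplotype_alignment(config)
        gapped = simulate_haplotype_alignment(
            SimulationConfig(seed=77, n_haplotypes=10, gap_columns=40))
        assert segregating_sites(gapped) <= segregating_sites(clean)


class TestSnpFrequency:
    @pytest.mark.parametrize("length,s,expected", [
        (4374, 243, 18),
        (133, 7, 19),
        (374, 25, 15),
        (1293, 62, 21),
        (2574, 149, 17),
    ])
    def test_published_region_frequencies(self, length, s, expected):
        assert snp_frequency(length, s) == expected

    def test_zero_snps_sentinel(self):
        assert snp_frequency(100, 0) is None

    def test_percent_polymorphism(self):
        assert percent_polymorphism(4374, 243) == pytest.approx(5.56, abs=0.005)


class TestDiversityTable:
    def test_region_s_values_sum_to_total(self, small_study):
        aln = small_study["alignment"]
        model = small_study["config"].gene_model
        table = diversity_table(aln, model,
                                classify_alignment_sites(aln, model))
        per_region = table[(table.partition == "all")
                           & ~table.region.isin(["total", "total_silent"])]
        total = table[(table.region == "total")
                      & (table.partition == "all")].iloc[0]
        assert per_region.S.sum() == total.S == segregating_sites(aln)

    def test_silent_plus_nonsynonymous_partition(self, small_study):
        aln = small_study["alignment"]
        model = small_study["config"].gene_model
        table = diversity_table(aln, model)
        totals = diversity_totals(table)
        silent = table[(table.region == "total_silent")
                       & (table.partition == "all")].iloc[0]
        total = table[(table.region == "total")
                      & (table.partition == "all")].iloc[0]
        assert silent.S + totals["S_nonsynonymous"] == total.S

    def test_exon_partition_lengths(self, small_study):
        """Per-exon synonymous + nonsynonymous site lengths equal the counted
        coding length of the exon."""
        aln = small_study["alignment"]
        model = small_study["config"].gene_model
        table = diversity_table(aln, model)
        for exon in [r.label for r in model.exon_regions]:
            sub = table[table.region == exon].set_index("partition")
            assert sub.loc["synonymous"].length_bp \
                + sub.loc["non_synonymous"].length_bp \
                <= sub.loc["all"].length_bp + 1e-9
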