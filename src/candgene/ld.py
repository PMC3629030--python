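"""Linkage disequilibrium from unphased genotypes.

Pairwise r² is computed from two-locus haplotype frequencies estimated by EM
over the double-heterozygote phase ambiguity, with permutation significance,
decay-with-distance fits (ordinary least squares and the drift-sampling
expected-r² curve of Hill & Weir), and detection of haplotype blocks as
maximal runs of consecutive SNPs with all pairwise r² above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import GenotypeMatrix

_EM_TOL = 1e-8
_EM_MAX_ITER = 200


class LDError(ValueError):
    pass


@dataclass(frozen=True)
class TwoLocusFrequencies:
    """EM haplotype frequencies for two biallelic loci (alleles A/a, B/b;
    the uppercase allele is the counted/dosage allele)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    log_likelihood: float
    n_iterations: int
    ll_trace: tuple = ()

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    @property
    def D(self) -> float:
        return self.p_AB - self.p_A * self.p_B

    @property
    def r2(self) -> float:
        pA, pB = self.p_A, self.p_B
        denom = pA * (1 - pA) * pB * (1 - pB)
        if denom <= 0:
            return float("nan")
        return self.D ** 2 / denom


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3×3 joint genotype counts over pairwise-complete individuals."""
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    tab = np.zeros((3, 3), dtype=float)
    np.add.at(tab, (a, b), 1.0)
    return tab


def _loglik(tab: np.ndarray, freqs: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3×3 genotype table."""
    pAB, pAb, paB, pab = freqs
    probs = np.array([
        [pab ** 2, 2 * paB * pab, paB ** 2],
        [2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB],
        [pAb ** 2, 2 * pAB * pAb, pAB ** 2],
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(np.nansum(np.where(tab > 0, tab * np.log(probs), 0.0)))


def _em_from_table(tab: np.ndarray, pi0: float,
                   track: bool = False) -> TwoLocusFrequencies:
    n_tot = tab.sum()
    n11 = tab[1, 1]
    # fixed haplotype contributions from unambiguous genotype classes
    base_AB = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    base_Ab = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    base_aB = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    base_ab = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    two_n = 2.0 * n_tot
    pi = pi0
    freqs = None
    prev = np.full(4, -1.0)
    it = 0
    trace: list[float] = []
    for it in range(1, _EM_MAX_ITER + 1):
        c = np.array([base_AB + n11 * pi, base_Ab + n11 * (1 - pi),
                      base_aB + n11 * (1 - pi), base_ab + n11 * pi])
        freqs = c / two_n
        pAB, pAb, paB, pab = freqs
        denom = pAB * pab + pAb * paB
        pi = 0.5 if denom <= 0 else pAB * pab / denom
        if track:
            trace.append(_loglik(tab, freqs))
        if np.max(np.abs(freqs - prev)) < _EM_TOL:
            break
        prev = freqs
    pAB, pAb, paB, pab = freqs
    ll = _loglik(tab, freqs)
    return TwoLocusFrequencies(pAB, pAb, paB, pab, ll, it, tuple(trace))


def em_two_locus_frequencies(g1: np.ndarray, g2: np.ndarray,
                             track: bool = False) -> TwoLocusFrequencies:
    """Two-locus haplotype frequencies by EM from unphased dosages.

    Runs from the linkage-equilibrium start plus coupling- and repulsion-
    biased starts; the highest-likelihood solution is kept, with ties broken
    in favour of D ≥ 0.  With ``track=True`` the per-iteration log-likelihood
    trace of the winning run is retained.
    """
    tab = _genotype_table(g1, g2)
    n = tab.sum()
    if n < 2:
        raise LDError("need ≥2 pairwise-complete individuals")
    pA = (2 * tab[2].sum() + tab[1].sum()) / (2 * n)
    pB = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise LDError("monomorphic locus: LD undefined")
    candidates = [_em_from_table(tab, pi0, track=track)
                  for pi0 in (0.5, 0.9, 0.1)]
    best = max(candidates,
               key=lambda f: (round(f.log_likelihood, 9), f.D >= 0))
    return best


def pairwise_r2(
    genotypes: GenotypeMatrix, with_d: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """All-pairs r² matrix and a long-format pair table.

    Returns ``(r2_matrix, pairs)`` where ``pairs`` has columns snp_i, snp_j,
    distance_bp, D, r2.  Monomorphic pairs yield NaN.
    """
    m = genotypes.n_snps
    if m < 2:
        raise LDError("need ≥2 loci")
    r2 = np.full((m, m), np.nan)
    np.fill_diagonal(r2, 1.0)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            try:
                f = em_two_locus_frequencies(genotypes.dosages[:, i],
                                             genotypes.dosages[:, j])
                rij, Dij = f.r2, f.D
            except LDError:
                rij, Dij = float("nan"), float("nan")
            r2[i, j] = r2[j, i] = rij
            dist = abs(int(genotypes.positions[i]) - int(genotypes.positions[j])) \
                if genotypes.positions[i] >= 0 and genotypes.positions[j] >= 0 \
                else -1
            rows.append({
                "snp_i": genotypes.snp_ids[i], "snp_j": genotypes.snp_ids[j],
                "i": i, "j": j, "distance_bp": dist, "D": Dij, "r2": rij,
            })
    return r2, pd.DataFrame(rows)


def r2_significance(
    genotypes: GenotypeMatrix,
    i: int,
    j: int,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for r² between loci i and j.

    One locus's genotypes are permuted across individuals; p uses the
    add-one correction p = (1 + #{perm r² ≥ observed}) / (1 + B).
    """
    if n_permutations < 100:
        raise LDError("need at least 100 permutations")
    g1 = genotypes.dosages[:, i].copy()
    g2 = genotypes.dosages[:, j]
    obs = em_two_locus_frequencies(g1, g2).r2
    if not np.isfinite(obs):
        return float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(g1)
        try:
            if em_two_locus_frequencies(g1, g2).r2 >= obs - 1e-12:
                count += 1
        except LDError:
            continue
    return (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# decay with distance
# ---------------------------------------------------------------------------

def hill_weir_expected_r2(C: np.ndarray, n: int) -> np.ndarray:
    """Drift-sampling expectation of r² at recombination parameter C = ρd
    for a sample of n sequences (Hill–Weir/Sved-style formula used for
    within-gene decay fitting)."""
    C = np.asarray(C, dtype=float)
    term1 = (10 + C) / ((2 + C) * (11 + C))
    term2 = 1 + ((3 + C) * (12 + 12 * C + C ** 2)) / (n * (2 + C) * (11 + C))
    return term1 * term2


@dataclass
class DecayFit:
    """LD-decay fits: OLS line and Hill–Weir expectation curve."""

    ols_intercept: float
    ols_slope: float
    hw_rho: float           # per-bp composite recombination parameter
    n_sequences: int
    max_distance: float

    def ols_at(self, d) -> np.ndarray:
        return self.ols_intercept + self.ols_slope * np.asarray(d, dtype=float)

    def hw_at(self, d) -> np.ndarray:
        return hill_weir_expected_r2(self.hw_rho * np.asarray(d, dtype=float),
                                     self.n_sequences)

    def distance_at_r2(self, threshold: float = 0.1,
                       model: str = "hill_weir") -> float | None:
        """Distance (bp) at which the fitted curve crosses ``threshold``;
        None when the curve never crosses within 100× the observed range."""
        lo, hi = 0.0, max(self.max_distance * 100.0, 1.0)
        f = self.hw_at if model == "hill_weir" else self.ols_at
        flo, fhi = float(f(lo)), float(f(hi))
        if flo <= threshold or fhi >= threshold:
            return None
        from scipy.optimize import brentq
        return float(brentq(lambda d: float(f(d)) - threshold, lo, hi))


def fit_ld_decay(pairs: pd.DataFrame, n_sequences: int) -> DecayFit:
    """Fit r²-vs-distance decay by OLS and by the Hill–Weir expectation.

    ``pairs`` must have finite ``distance_bp`` ≥ 0 and ``r2`` columns;
    ``n_sequences`` is the number of sampled chromosomes (2 × individuals
    for unphased diploid data).
    """
    d = pairs["distance_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    ok = np.isfinite(d) & np.isfinite(r2) & (d >= 0)
    d, r2 = d[ok], r2[ok]
    if len(np.unique(d)) < 3:
        raise LDError("need ≥3 pairs with distinct distances")
    slope, intercept = np.polyfit(d, r2, 1)

    def resid(log_rho):
        return hill_weir_expected_r2(np.exp(log_rho) * d, n_sequences) - r2

    sol = optimize.least_squares(resid, x0=np.log(1e-3),
                                 bounds=(np.log(1e-10), np.log(10.0)))
    return DecayFit(float(intercept), float(slope), float(np.exp(sol.x[0])),
                    n_sequences, float(d.max()))


# ---------------------------------------------------------------------------
# haplotype blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeBlock:
    """Inclusive run [start, end] of consecutive SNP indices in map order."""

    start_snp_index: int
    end_snp_index: int

    @property
    def size(self) -> int:
        return self.end_snp_index - self.start_snp_index + 1


def detect_blocks(
    r2_matrix: np.ndarray,
    threshold: float = 0.75,
    p_matrix: np.ndarray | None = None,
    p_threshold: float = 0.001,
) -> list[HaplotypeBlock]:
    """Maximal non-overlapping runs of ≥2 consecutive SNPs in which every
    within-run pair has r² > threshold (and permutation p < p_threshold if a
    p-value matrix is supplied)."""
    m = r2_matrix.shape[0]

    def ok(i: int, j: int) -> bool:
        if not (r2_matrix[i, j] > threshold):
            return False
        if p_matrix is not None and not (p_matrix[i, j] < p_threshold):
            return False
        return True

    blocks: list[HaplotypeBlock] = []
    i = 0
    while i < m - 1:
        j = i
        while j + 1 < m and all(ok(k, j + 1) for k in range(i, j + 1)):
            j += 1
        if j > i:
            blocks.append(HaplotypeBlock(i, j))
            i = j + 1
        else:
            i += 1
    return blocks
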