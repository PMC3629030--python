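"""Synthetic data generation for the candidate-gene association pipeline.

Generates every input the analysis consumes, with the statistical structure
the study design assumes: a coalescent haplotype alignment over the gene
model (for diversity analysis), a structured association panel of diploid
genotypes with Balding–Nichols subpopulation differentiation and
distance-decaying LD (for the Q+K scan), quantitative traits with planted
marker effects plus a kinship-structured polygenic background, and a
full-sib F1 validation cross.

All generators are deterministic given (seed, config); per-generator random
streams are derived from the master seed by stable hashing of the generator
name.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignmentSet
from .genemodel import GeneModel
from .genotypes import GenotypeMatrix
from .datasets import ptuxs1_gene_model

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


class SimulationError(ValueError):
    pass


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-generator seed below 2^31 derived from the master seed."""
    return zlib.crc32(f"{master_seed}:{name}".encode()) % (2 ** 31 - 1) + 1


@dataclass(frozen=True)
class QTLSpec:
    """A planted marker effect: additive effect a (half the homozygote
    difference) and dominance deviation d (heterozygote deviation), both in
    trait units, at one SNP for one trait."""

    snp_index: int
    trait_index: int
    additive_effect: float
    dominance_effect: float = 0.0


def default_qtl_specs() -> list[QTLSpec]:
    """Planted effects spanning the study's observed standardized-effect
    range (2a/s_p roughly 0.1-0.9), with additive and dominance components."""
    return [
        QTLSpec(9, 2, 0.35, 0.10),
        QTLSpec(5, 3, 0.50, 0.25),
        QTLSpec(26, 4, 0.55, 0.0),
        QTLSpec(67, 5, 0.30, 0.28),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults emulate the published design: 88 haplotypes (2 × 44 sequenced
    individuals) over the 4374-bp gene, 82 common SNPs (MAF > 0.10)
    genotyped in 426 individuals from 3 geographic subpopulations
    (180/86/160), 10 quantitative traits, and a 1200-progeny F1 cross.
    """

    seed: int = 1
    n_haplotypes: int = 88
    theta_per_site: float = 0.01
    gene_model: GeneModel = field(default_factory=ptuxs1_gene_model)
    n_individuals: int = 426
    subpop_proportions: tuple[float, ...] = (180 / 426, 86 / 426, 160 / 426)
    fst: float = 0.05
    ld_decay_scale: float = 400.0
    n_snps: int = 82
    maf_min: float = 0.10
    qtl_effects: tuple[QTLSpec, ...] = field(
        default_factory=lambda: tuple(default_qtl_specs()))
    h2_polygenic: float = 0.3
    noise_sd: float = 1.0
    n_traits: int = 10
    n_progeny: int = 1200
    n_families: int = 0
    family_size: int = 2
    gap_columns: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-12:
            raise SimulationError("subpop_proportions must sum to 1")
        if min(self.subpop_proportions) <= 0:
            raise SimulationError("subpop_proportions must be positive")
        for name in ("n_haplotypes", "n_individuals", "n_snps", "n_traits",
                     "n_progeny"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.theta_per_site < 0:
            raise SimulationError("theta_per_site must be non-negative")
        if not 0.0 <= self.fst < 1.0:
            raise SimulationError("fst must be in [0, 1)")
        if self.ld_decay_scale <= 0:
            raise SimulationError("ld_decay_scale must be positive")
        if not 0.0 < self.maf_min < 0.5:
            raise SimulationError("maf_min must be in (0, 0.5)")
        if not 0.0 <= self.h2_polygenic < 1.0:
            raise SimulationError("h2_polygenic must be in [0, 1)")
        for q in self.qtl_effects:
            if not 0 <= q.snp_index < self.n_snps:
                raise SimulationError(f"QTL snp_index {q.snp_index} out of range")
            if not 0 <= q.trait_index < self.n_traits:
                raise SimulationError(f"QTL trait_index {q.trait_index} out of range")


# ---------------------------------------------------------------------------
# haplotype alignment
# ---------------------------------------------------------------------------

def simulate_haplotype_alignment(config: SimulationConfig) -> AlignmentSet:
    """Coalescent haplotype alignment over the gene model.

    A single non-recombining coalescent genealogy is simulated for
    ``n_haplotypes`` haploid samples and mutations are laid down at rate
    θ/2 per site on the coalescent time scale, so the expected pairwise
    diversity per site equals ``theta_per_site``.  Sites hit more than once
    (violating the infinite-sites idealisation) are reverted so every
    polymorphic column is biallelic.  Optionally, ``gap_columns`` random
    columns receive gap characters to exercise the indel-exclusion rules.
    """
    L = config.gene_model.total_length
    if L <= 0:
        raise SimulationError("gene model has non-positive length")
    rng = np.random.default_rng(derive_seed(config.seed, "alignment"))
    ref = _BASES[rng.integers(0, 4, size=L)]
    # give the reference a realistic open reading frame: random non-stop
    # codons along the CDS, terminated by a stop codon
    cds_pos = config.gene_model.cds_positions()
    if len(cds_pos) >= 3:
        sense = [c for c in _SENSE_CODONS]
        for k in range(0, len(cds_pos) - 3, 3):
            codon = sense[rng.integers(len(sense))]
            for o in range(3):
                ref[cds_pos[k + o]] = codon[o:o + 1].encode()
        stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        for o in range(3):
            ref[cds_pos[len(cds_pos) - 3 + o]] = stop[o:o + 1].encode()
    matrix = np.tile(ref, (config.n_haplotypes, 1))

    if config.theta_per_site > 0:
        ts = msprime.sim_ancestry(
            samples=config.n_haplotypes, ploidy=1, population_size=1.0,
            sequence_length=L,
            random_seed=derive_seed(config.seed, "ancestry"),
        )
        # infinite-sites mutations at continuous positions: every variant is
        # biallelic and the segregating-site count is unsaturated
        mts = msprime.sim_mutations(
            ts, rate=config.theta_per_site / 2.0, discrete_genome=False,
            random_seed=derive_seed(config.seed, "mutations"),
        )
        if mts.num_sites > L:
            raise SimulationError(
                f"{mts.num_sites} mutations exceed the {L} available sites")
        used: set[int] = set()
        for var in mts.variants():
            pos = int(var.site.position)
            while pos in used:  # integer-grid collision: move to a free slot
                pos = int(rng.integers(L))
            used.add(pos)
            anc_b = var.alleles[0].encode()
            der_b = var.alleles[1].encode()
            # anchor the column to the reference base; keep the derived state
            # distinct from it
            if der_b == ref[pos]:
                der_b = anc_b if anc_b != ref[pos] else _BASES[
                    (int(np.flatnonzero(_BASES == ref[pos])[0]) + 1) % 4]
            carriers = var.genotypes == 1
            matrix[carriers, pos] = der_b
            matrix[~carriers, pos] = ref[pos]

    if config.gap_columns > 0:
        cols = rng.choice(L, size=min(config.gap_columns, L), replace=False)
        for c in cols:
            k = rng.integers(1, config.n_haplotypes)
            rows = rng.choice(config.n_haplotypes, size=k, replace=False)
            matrix[rows, c] = b"-"

    names = [f"hap{i + 1}" for i in range(config.n_haplotypes)]
    return AlignmentSet(names, matrix)


# ---------------------------------------------------------------------------
# structured association panel
# ---------------------------------------------------------------------------

def _subpop_sizes(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n individuals to subpopulations."""
    raw = [p * n for p in proportions]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - x for s, x in zip(sizes, raw)])
    for k in order[:rem]:
        sizes[k] += 1
    return sizes


def _balding_nichols_freqs(rng, p0: np.ndarray, fst: float,
                           n_subpops: int) -> np.ndarray:
    """Subpopulation allele frequencies: Beta((1−F)/F·p, (1−F)/F·(1−p))."""
    if fst == 0:
        return np.tile(p0, (n_subpops, 1))
    c = (1.0 - fst) / fst
    return rng.beta(c * p0, c * (1.0 - p0), size=(n_subpops, len(p0)))


def simulate_structured_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Diploid genotype panel with subpopulation structure and decaying LD.

    Haplotypes are generated by thresholding a stationary latent Gaussian
    process with correlation 2^(−d/ld_decay_scale) in base pairs at the
    per-SNP, per-subpopulation allele-frequency quantile; subpopulation
    frequencies follow the Balding–Nichols model.  Optionally the first
    ``n_families × family_size`` individuals form full-sib families, and
    the returned kinship holds the pedigree relationship (0.5 for full
    sibs, 1 on the diagonal); with no families it is the identity.

    Returns ``(genotypes, Q, K)`` with Q the one-hot true-membership matrix.
    All realized minor-allele frequencies are ≥ maf_min (the whole panel is
    redrawn on failure, with a bounded number of retries).
    """
    rng = np.random.default_rng(derive_seed(config.seed, "population"))
    L = config.gene_model.total_length
    m, n = config.n_snps, config.n_individuals
    if m < 2:
        raise SimulationError("need at least 2 SNPs")
    if m > L:
        raise SimulationError("more SNPs than base pairs")
    positions = np.sort(rng.choice(L, size=m, replace=False))

    dist = np.abs(positions[:, None] - positions[None, :]).astype(float)
    corr = np.power(2.0, -dist / config.ld_decay_scale)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))

    sizes = _subpop_sizes(n, config.subpop_proportions)
    membership = np.repeat(np.arange(len(sizes)), sizes)
    n_subpops = len(sizes)

    last_bad = None
    for _attempt in range(20):
        # per-SNP ancestral and subpopulation frequencies, constrained so the
        # mixture frequency leaves headroom over the MAF floor
        p_sub = np.empty((n_subpops, m))
        for j in range(m):
            for _ in range(200):
                p0 = rng.uniform(0.2, 0.8)
                ps = _balding_nichols_freqs(rng, np.array([p0]), config.fst,
                                            n_subpops)[:, 0]
                mix = float(np.dot(np.asarray(sizes) / n, ps))
                if config.maf_min + 0.05 <= mix <= 1 - config.maf_min - 0.05:
                    p_sub[:, j] = ps
                    break
            else:
                raise SimulationError(
                    f"could not satisfy MAF constraint for SNP index {j}")
        thresholds = stats.norm.ppf(np.clip(p_sub, 1e-9, 1 - 1e-9))

        def draw_haplotype(subpop: int) -> np.ndarray:
            z = chol @ rng.standard_normal(m)
            return (z < thresholds[subpop]).astype(float)

        dosages = np.empty((n, m))
        n_fam_ind = config.n_families * config.family_size
        i = 0
        K = np.eye(n)
        for fam in range(config.n_families):
            sp = int(membership[min(i, n - 1)])
            parents = [(draw_haplotype(sp), draw_haplotype(sp))
                       for _ in range(2)]
            members = []
            for _k in range(config.family_size):
                if i >= n:
                    break
                h1 = parents[0][rng.integers(2)]
                h2 = parents[1][rng.integers(2)]
                dosages[i] = h1 + h2
                members.append(i)
                i += 1
            for a in members:
                for b in members:
                    if a != b:
                        K[a, b] = 0.5
        while i < n:
            sp = int(membership[i])
            dosages[i] = draw_haplotype(sp) + draw_haplotype(sp)
            i += 1

        freqs = dosages.mean(axis=0) / 2.0
        maf = np.minimum(freqs, 1 - freqs)
        if (maf >= config.maf_min).all():
            break
        last_bad = int(np.argmin(maf))
    else:
        raise SimulationError(
            f"MAF constraint unsatisfied after retries (SNP index {last_bad})")

    Q = np.zeros((n, n_subpops))
    Q[np.arange(n), membership] = 1.0
    snp_ids = [f"SNP{j + 1}" for j in range(m)]
    individuals = [f"ind{i + 1}" for i in range(n)]
    genotypes = GenotypeMatrix(dosages, individuals, snp_ids, positions)
    return genotypes, Q, K


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    kinship: np.ndarray | None,
    qtl: list[QTLSpec] | tuple[QTLSpec, ...],
    h2_polygenic: float,
    noise_sd: float,
    seed: int,
    n_traits: int = 10,
    mu: float = 0.0,
) -> pd.DataFrame:
    """Quantitative traits from planted marker effects, a polygenic term and
    independent noise.

    y = µ + Σ_qtl [a·(dosage−1) + d·1{dosage=1}] + g + e, with
    g ~ N(0, σ²_a·K) where σ²_a = noise_sd²·h2/(1−h2) (so h2 is the
    polygenic fraction of the non-QTL variance) and e ~ N(0, noise_sd²·I).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    if kinship is None:
        kinship = np.eye(n)
    kinship = np.asarray(kinship, dtype=float)
    if kinship.shape != (n, n):
        raise SimulationError("kinship dimension mismatch")
    if not np.allclose(kinship, kinship.T, atol=1e-10):
        raise SimulationError("kinship must be symmetric")
    eigs = np.linalg.eigvalsh(kinship)
    if eigs.min() < -1e-8:
        raise SimulationError(
            f"kinship not PSD: min eigenvalue {eigs.min():.3e}")

    Y = np.full((n, n_traits), mu)
    for q in qtl:
        dose = genotypes.dosages[:, q.snp_index]
        add = np.where(np.isfinite(dose), dose - 1.0, 0.0)
        dom = np.where(dose == 1.0, 1.0, 0.0)
        Y[:, q.trait_index] = Y[:, q.trait_index] \
            + q.additive_effect * add + q.dominance_effect * dom

    if h2_polygenic > 0 and noise_sd > 0:
        sigma_a = noise_sd * np.sqrt(h2_polygenic / (1.0 - h2_polygenic))
        chol = np.linalg.cholesky(kinship + 1e-8 * np.eye(n))
        Y += sigma_a * (chol @ rng.standard_normal((n, n_traits)))
    if noise_sd > 0:
        Y += noise_sd * rng.standard_normal((n, n_traits))
    return pd.DataFrame(Y, index=genotypes.individuals,
                        columns=[f"trait_{t + 1}" for t in range(n_traits)])


# ---------------------------------------------------------------------------
# F1 validation cross
# ---------------------------------------------------------------------------

def simulate_f1_cross(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_progeny: int,
    seed: int,
    snp_ids: list[str] | None = None,
    positions: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Mendelian F1 full-sib progeny from two genotyped parents.

    Each progeny genotype is the sum of one gamete per parent, independent
    across loci (no within-cross linkage).  Loci with a missing parent
    genotype are skipped with a warning.
    """
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape:
        raise SimulationError("parents genotyped at different loci")
    ok = np.isfinite(p1) & np.isfinite(p2)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} locus/loci skipped: missing parent genotype")
    keep = np.flatnonzero(ok)
    rng = np.random.default_rng(seed)

    def gametes(par: np.ndarray) -> np.ndarray:
        out = np.empty((n_progeny, len(keep)))
        for col, j in enumerate(keep):
            if par[j] == 0:
                out[:, col] = 0.0
            elif par[j] == 2:
                out[:, col] = 1.0
            else:
                out[:, col] = rng.integers(0, 2, size=n_progeny)
        return out

    dosages = gametes(p1) + gametes(p2)
    snp_ids = snp_ids or [f"SNP{j + 1}" for j in range(len(p1))]
    snp_ids = [snp_ids[j] for j in keep]
    positions = None if positions is None else np.asarray(positions)[keep]
    individuals = [f"F1_{i + 1}" for i in range(n_progeny)]
    return GenotypeMatrix(dosages, individuals, snp_ids, positions)


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

def genotypes_from_haplotypes(
    alignment: AlignmentSet, maf_min: float = 0.10, seed: int = 0
) -> GenotypeMatrix:
    """Diploid genotypes by random pairing of simulated haplotypes at the
    common biallelic segregating columns (the end-to-end coupling mode)."""
    from .diversity import usable_columns

    n_hap = alignment.n_sequences
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_hap)
    n_ind = n_hap // 2
    cols, dosage_cols, ids, pos = [], [], [], []
    usable = usable_columns(alignment) & (alignment.n_alleles() == 2)
    for j in np.flatnonzero(usable):
        counts = alignment.allele_counts(int(j))
        alleles = sorted(counts, key=lambda a: counts[a])
        minor = alleles[0]
        freq = counts[minor] / n_hap
        if freq <= maf_min:
            continue
        carrier = (alignment.matrix[:, j] == minor).astype(float)
        dosage = carrier[order[:n_ind * 2:2]] + carrier[order[1:n_ind * 2:2]]
        dosage_cols.append(dosage)
        pos.append(int(j))
    if not dosage_cols:
        raise SimulationError("no common SNPs in alignment")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(
        dosages, [f"ind{i + 1}" for i in range(n_ind)],
        [f"SNP{k + 1}" for k in range(dosages.shape[1])],
        np.array(pos),
    )


def simulate_study(config: SimulationConfig) -> dict:
    """Generate the full synthetic study: alignment, panel, traits, truth
    table and the F1 validation set.  Returns a dict of artifacts."""
    alignment = simulate_haplotype_alignment(config)
    genotypes, Q, K = simulate_structured_population(config)
    phenotypes = simulate_phenotypes(
        genotypes, K, list(config.qtl_effects), config.h2_polygenic,
        config.noise_sd, derive_seed(config.seed, "phenotypes"),
        n_traits=config.n_traits,
    )
    truth = pd.DataFrame(
        [{
            "snp_id": genotypes.snp_ids[q.snp_index],
            "snp_index": q.snp_index,
            "trait": phenotypes.columns[q.trait_index],
            "additive_effect": q.additive_effect,
            "dominance_effect": q.dominance_effect,
        } for q in config.qtl_effects]
    )

    rng = np.random.default_rng(derive_seed(config.seed, "parents"))
    freqs = genotypes.allele_freq()
    parent1 = rng.binomial(2, freqs).astype(float)
    parent2 = rng.binomial(2, freqs).astype(float)
    progeny = simulate_f1_cross(
        parent1, parent2, config.n_progeny,
        derive_seed(config.seed, "cross"),
        snp_ids=list(genotypes.snp_ids), positions=genotypes.positions,
    )
    progeny_qtl = [
        q for q in config.qtl_effects
        if genotypes.snp_ids[q.snp_index] in progeny.snp_ids
    ]
    remapped = [
        replace(q, snp_index=progeny.snp_ids.index(
            genotypes.snp_ids[q.snp_index]))
        for q in progeny_qtl
    ]
    progeny_phenotypes = simulate_phenotypes(
        progeny, None, remapped, 0.0, config.noise_sd,
        derive_seed(config.seed, "progeny-phenotypes"),
        n_traits=config.n_traits,
    )
    return {
        "config": config,
        "alignment": alignment,
        "genotypes": genotypes,
        "Q": Q,
        "K": K,
        "phenotypes": phenotypes,
        "truth": truth,
        "parent1": parent1,
        "parent2": parent2,
        "progeny": progeny,
        "progeny_phenotypes": progeny_phenotypes,
    }
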