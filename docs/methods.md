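# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `candgene` package. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Gene model and variant annotation

A gene is a partition of `[0, L)` into ordered 5′UTR / exon / intron / 3′UTR
regions (0-based half-open internally; 1-based only at the GFF3 boundary).
The bundled `PtUXS1` layout is 133 bp 5′UTR, seven exons totalling 1293 bp
of coding sequence, six introns totalling 2574 bp, and 374 bp of 3′UTR
(L = 4374). The concatenated exon length minus the frame offset must be
divisible by 3.

Coding variants are classified against the majority-consensus codon context
(ties broken alphabetically): synonymous if the amino acid is preserved,
nonsense if the alternate codon is a stop, missense otherwise, under the
standard nuclear code. The consensus is used because candidate-gene panels
rarely designate a reference allele; a designated-reference mode would only
change classifications at sites where the consensus differs from that
reference. Nonsense variants are pooled with missense as "non-synonymous"
in all tabulations. Variants whose consensus context is a stop codon
(normally only the terminal stop) are classified synonymous when the stop
is retained and non-synonymous when it is lost.

Synonymous/nonsynonymous site denominators use Nei–Gojobori fractional
counting per base: position k of a codon contributes (number of the 3
possible changes at k that preserve the amino acid)/3 synonymous sites;
stop-creating changes count as nonsynonymous. Summed over a region this
partitions the counted coding length exactly, which is what makes fractional
region lengths (e.g. 143.83 synonymous sites in a 609-bp exon) meaningful.
Codons containing gap characters and the terminal stop codon contribute no
sites. There is no Jukes–Cantor or other multiple-hit correction anywhere:
within-species diversity at these scales is far from saturation, and the
raw-proportion convention matches standard polymorphism-table practice.

## Diversity statistics

All statistics use only usable columns: gap-free and at most biallelic.
Columns with more than two alleles are excluded with a warning (the analysis
treats SNPs as biallelic throughout), and the per-site denominators exclude
the same columns, so π and θw are internally consistent. Singletons count
as segregating; the MAF > 0.10 "common SNP" filter applies only to the
genotyped association panel, never to sequence diversity.

- S: count of usable biallelic segregating columns.
- π: total pairwise differences / (n(n−1)/2 · L_usable).
- θw: S / (a_{n−1} · L_usable), a_{n−1} the harmonic number.
- bp-per-SNP: round(length/S), half away from zero; undefined at S = 0.

Display rounding follows polymorphism-table convention: percent
polymorphism to 2 dp, π and θw to 5 dp. Both estimators are checked against
brute-force enumeration oracles at tolerance 1e-12, and θw against its own
generating parameter over 200 simulated 44-haplotype alignments.

## LD

Two-locus haplotype frequencies are estimated from unphased diploid dosages
by EM over the double-heterozygote ambiguity (equilibrium initialisation,
tolerance 1e-8, ≤ 200 iterations). Because the likelihood can have two
symmetric optima when the data cannot distinguish coupling from repulsion,
EM is additionally started from coupling- and repulsion-biased points; the
best likelihood wins and exact ties resolve to the D ≥ 0 solution (r² is
identical either way, so the tie-break only fixes the sign of D
deterministically). r² = D²/(p_A p_a p_B p_b). Permutation significance
shuffles one locus across individuals with the add-one correction
p = (1 + #{r²_perm ≥ r²_obs})/(1 + B). Tests and the pipeline default to
B in the hundreds-to-1000 range; the original analysis scale (10⁵) is
available through the same parameter — the estimate is unbiased at any B,
only the Monte-Carlo resolution changes.

Decay with distance is fitted two ways, because a "least-squares fit of r²
to its expectation" is ambiguous between them: (a) OLS of r² on distance,
and (b) the Hill–Weir drift-sampling expectation
E[r²] = [(10+C)/((2+C)(11+C))]·[1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]
with C = ρd, fitted over log ρ with bounded least squares (n = number of
sampled chromosomes, 2× individuals for unphased data). Both fits report
the distance at which they cross a threshold (default r² = 0.1), found by
bracketed root-finding up to 100× the observed distance range, else
"beyond range".

Haplotype blocks are maximal runs of ≥ 2 consecutive SNPs (map order) in
which **every** within-run pair exceeds the r² threshold (default 0.75),
optionally gated on permutation p < 0.001. The all-pairs rule is a
documented convention: published block listings give contiguous index
ranges without defining an algorithm, and the all-pairs rule is the
strictest definition consistent with them. Output depends only on the
exceeds-threshold predicate, not on the r² magnitudes above it.

## Q+K mixed model

The single-marker model is y = Xβ + u + e with X = [1, Q(one column
dropped), marker], Var(u) = σ²_a K, Var(e) = σ²_e I. Dropping one Q column
avoids collinearity with the intercept since membership rows sum to 1. K is
eigendecomposed once per scan; the variance structure is parameterised by
h = σ²_a/(σ²_a + σ²_e) so rotated observations have weights
w_i = h·s_i + (1−h). The REML criterion (profiling the total variance) is
minimised over h ∈ [0, 0.999] by a 64-point grid with local bounded
refinement — the 1-D REML surface for this model is smooth and the grid
guards against local minima at negligible cost. At h = 0 the fit **is**
ordinary least squares, which provides an exact oracle: the marker Wald
F-test (1, n−p df) reproduces the OLS p-value to machine precision at that
boundary. The marker's explained variance is reported as
100·var(marker·β̂)/var(y). Individuals missing the trait or the marker are
dropped per test (complete-case; no imputation); when that changes the
sample the kinship eigendecomposition is redone on the subset. Analytic
F tests are the default; permutation p-values for the MLM would multiply
runtime by the permutation count for no change in calibration, which the
null-calibration tests verify directly.

Kinship is the marker-based Ritland correlation estimator: per biallelic
locus, (x_i − p)(x_j − p)/(p(1−p)) with x = dosage/2 and p the sample
frequency, averaged over polymorphic loci and doubled to the relationship
scale (self-similarity 1, full sibs 0.5) that the unit-diagonal K of the
mixed model expects. Negative pairwise estimates truncate to 0 and the
diagonal is set to 1 — the usual convention in Q+K practice. The truncation
makes the null mean slightly positive (≈ 0.4·sd of the estimator), which is
why noise bounds on unrelated panels are only meaningful with several
hundred loci.

## Multiple testing

Storey q-values: π̂0 from the λ-grid {0, 0.05, …, 0.90} with a cubic
smoothing spline evaluated at the largest λ, clamped to (0, 1]; then
q_i = min_{t ≥ p_i} π̂0·m·t/#{p ≤ t} via the monotone step-up recursion.
With π0 = 1 the output equals Benjamini–Hochberg exactly (verified against
an independent implementation). Q-value families are per trait across SNPs
by default — matching trait-wise reporting of candidate-gene scans — with a
global-family option.

## Gene action

For a significant (SNP, trait) pair with genotype-class means G_BB (minor
homozygote), G_Bb, G_bb: 2a = |G_BB − G_bb|, d = G_Bb − ½(G_BB + G_bb),
d/a signed with a > 0, standardized effect 2a/s_p. Mode: additive
|d/a| ≤ 0.5, dominant 0.5 < |d/a| < 1.25, overdominant |d/a| > 1.25; the
measure-zero boundary |d/a| = 1.25, left open by the published thresholds,
is assigned overdominant. The additive-effect column follows the published
formula a = p_B·G_BB + p_b·G_Bb − G verbatim (B = minor allele) even though
it omits a G_bb term; a `corrected` option provides the
genotype-frequency-weighted version p_B²·G_BB + 2p_Bp_b·G_Bb + p_b²·G_bb − G
for users who consider the printed formula a typo. Records are only
emitted when all three genotype classes are observed.

## Haplotype trend regression

Windows of 3 consecutive SNPs (configurable) are phased probabilistically by
EM over the ≤ 2^w haplotypes (equilibrium initialisation, tolerance 1e-8,
≤ 500 iterations, individuals grouped by genotype pattern). Each individual
receives posterior expected haplotype counts summing to 2; these dosages —
not best-guess phases — are the regressors, the construction that makes the
test a *trend* regression and keeps it deterministic. Haplotypes at
frequency ≤ 1% are excluded from testing; the most frequent haplotype is
the dropped reference for identifiability. Window significance is a
permutation F test on the trait (vectorised over permutations; add-one
correction); per-haplotype p-values from single regressions are reported
alongside because published haplotype listings include haplotypes inside
windows whose joint test is not significant. Individuals missing any
genotype in the window are excluded from that window.

## Validation population

Loci are screened against the Mendelian expectation of the cross (1:2:1 for
het × het, 1:1 for het × hom, all-heterozygous for AA × aa) by Pearson χ²
with df = expected classes − 1, kept at p ≥ 0.01. Crosses between
identically homozygous parents are uninformative and skipped; for the
single-class AA × aa expectation any off-type progeny is a violation
(p = 0). Surviving loci enter a one-way fixed-effects ANOVA per trait with
R² = 100·SS_marker/SS_total and per-trait Storey FDR. The panel forwarded
to validation is exactly the discovery SNPs with p < 0.05.

## Synthetic-data generator

The generator's defaults are the study conditions: 88 haplotypes (2 × 44
individuals) at θ = 0.01/site over the 4374-bp gene model; 426 individuals
in three subpopulations of 180/86/160; 82 SNPs with every realized
MAF ≥ 0.10; 10 traits; 1200 F1 progeny.

**Alignment.** A single non-recombining coalescent genealogy (msprime,
haploid samples, population size scaled so pairwise diversity per site
equals θ) with infinite-sites mutations at continuous positions mapped to
distinct integer columns (grid collisions, rare at these densities, move to
a random free column). No recombination within the gene is the conservative
choice for a 4.4-kb locus and makes every column share one genealogy. The
reference carries a stop-free open reading frame ending in a stop codon, so
consensus-context annotation behaves as on a real gene. Optional gap
columns exercise the indel-exclusion rules. Mutations are neutral:
synonymous and nonsynonymous diversity are equal in expectation, so
selection-driven signatures (π_nonsyn/π_syn ≪ 1) are *not* reproduced and
tests assert only arithmetic, not selection.

**Panel.** Subpopulation allele frequencies follow Balding–Nichols
(Beta((1−F)/F·p, (1−F)/F·(1−p)), default Fst = 0.05, a modest
among-region differentiation typical of outcrossing trees). Haplotypes are
generated by thresholding a stationary latent Gaussian with correlation
2^(−d/scale) in bp at the per-SNP frequency quantile; the default
scale = 400 bp makes fitted r² fall below 0.1 within several hundred bp,
the qualitative decay of a low-LD outcrossing species, without a
coalescent-with-recombination model. Ancestral frequencies are drawn so the
mixture frequency leaves ≥ 0.05 headroom over the MAF floor; the whole
panel is redrawn (bounded retries) if any realized MAF still falls below
0.10. Optional full-sib families give the pedigree K (0.5 off-diagonal
within families); otherwise K is the identity. The 44-haplotype alignment
and the 426-individual panel are generated independently by default — how
the published panel relates statistically to its discovery individuals is
unstated, so the package also offers `genotypes_from_haplotypes` to couple
them for end-to-end runs.

**Traits.** y = µ + Σ[a·(dosage−1) + d·1{dosage=1}] + g + e with
g ~ N(0, σ²_a K), e ~ N(0, noise_sd² I) and
σ²_a = noise_sd²·h2/(1−h2), i.e. `h2_polygenic` is the polygenic fraction
of the non-QTL variance (default 0.3, a mid-range single-trait
heritability for growth/wood traits). Default planted effects span
standardized effects 2a/s_p ≈ 0.1–0.9, the range observed in
candidate-gene studies of this kind, with both additive and dominance
components.

**Cross.** Each progeny is one Mendelian gamete per parent, independent
across loci — no within-cross linkage, which overstates the information of
the validation set relative to a real linkage map but leaves the per-locus
tests exact. Progeny traits use the same planted effects with independent
noise (no polygenic term: full-sib polygenic covariance would only shrink
effective replication).

All generators derive their streams from one master seed by stable hashing
of the generator name (CRC32, kept below 2³¹), so runs are bit-reproducible
given (seed, config) and stages can be re-run independently.

What passing tests therefore show: the estimators are correct against
independent oracles, calibrated under their own nulls, and powerful at the
planted effect sizes **under the generator's assumptions** — Gaussian
traits, exponential-decay LD, Balding–Nichols structure, no genotyping
error, no missingness by default. They do not show robustness to selection,
non-normal traits, genotyping error, or cryptic relatedness beyond what K
captures.

## Problem sizes and numerical choices

Monte-Carlo sizes in the acceptance tests were fixed once at the scale the
contracts state: 200 alignments for θw recovery, 50 random datasets for the
OLS-boundary oracle, 2000 replicates for MLM and HTR null calibration (3
binomial-SE tolerance), 50 seeds for power at 2a/s_p ≥ 0.9, 20 seeds for
LD-decay recovery (15% on the r² = 0.1 crossing), 1000 crosses for the
Mendelian screen size. EM tolerances are 1e-8 on frequencies; the REML grid
is 64 points with 1e-8 bounded refinement; permutation p-values always use
the add-one correction and an explicit seed.

## Known limitations

- Fractional published region lengths (e.g. 143.83 synonymous sites) and
  the headline diversity values of the original study cannot be re-derived
  without the deposited alleles; only internal arithmetic and estimator
  properties are reproducible, and the acceptance machinery is scoped
  accordingly.
- The latent-Gaussian LD model produces smooth monotone decay; it cannot
  produce the block-punctuated mosaic of recombination hotspots.
- The EM r² pipeline is O(m²) in SNPs with a Python inner loop — adequate
  for candidate-gene panels (82 SNPs ≈ seconds), not for genome-wide data.
- STRUCTURE/ADMIXTURE-style ancestry inference is out of scope: Q is an
  input (the generator supplies true memberships).
- Alternative genetic codes, splice variants and epistatic or multi-locus
  models are not supported.
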