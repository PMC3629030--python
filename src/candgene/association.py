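"""Candidate-gene association analysis.

Single-marker Q+K mixed-model scans with Storey q-value multiple-testing
control, marker-based Ritland kinship, gene-action decomposition (2a, d,
d/a, 2a/s_p) with mode classification, and validation-population tests
(Mendelian segregation χ² and fixed-effects single-marker ANOVA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .genotypes import GenotypeMatrix
from .mixedmodel import KinshipEigen, MLMError, MLMFit, mlm_single_marker


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ritland marker-based kinship
# ---------------------------------------------------------------------------

def ritland_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """Marker-based Ritland relatedness estimator.

    For a biallelic locus with sample allele frequency p, the per-locus
    contribution for individuals i, j with allele frequencies x = dosage/2 is
    (x_i − p)(x_j − p) / (p(1−p)), averaged over polymorphic loci and doubled
    so the estimate is on the relationship scale of the unit-diagonal K the
    mixed model consumes (self-similarity 1, full sibs 0.5).  Negative
    pairwise estimates are truncated to 0 and the diagonal is set to 1, the
    convention of Q+K association practice.
    """
    X = genotypes.dosages / 2.0
    n, m = X.shape
    if n < 2:
        raise AssociationError("need ≥2 individuals")
    p = np.nanmean(X, axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise AssociationError("all loci monomorphic")
    Xp = X[:, poly] - p[poly]
    denom = p[poly] * (1 - p[poly])
    Z = np.where(np.isnan(Xp), 0.0, Xp / np.sqrt(denom))
    counts = (~np.isnan(Xp)).astype(float)
    num = Z @ Z.T
    cnt = counts @ counts.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = 2.0 * num / cnt
    K = np.where(K < 0, 0.0, K)
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p_values: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """π0 estimate by the λ-grid method with cubic-spline smoothing.

    π0(λ) = #{p > λ} / (m(1−λ)) over λ ∈ {0, 0.05, …, 0.90}; a smoothing
    spline is evaluated at the largest λ and the result capped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                           for lam in lambdas])
    if len(lambdas) >= 4:
        spl = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
        pi0 = float(spl(lambdas[-1]))
    else:
        pi0 = float(pi0_lambda[-1])
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey positive-FDR q-values.

    q_i = min_{t ≥ p_i} π0·m·t / #{p ≤ t}.  With ``pi0=1`` the result equals
    the Benjamini–Hochberg step-up adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# gene action
# ---------------------------------------------------------------------------

ADDITIVE = "additive"
DOMINANT = "dominant"
OVERDOMINANT = "overdominant"


@dataclass(frozen=True)
class GeneActionRecord:
    """Gene-action decomposition of a marker-trait association.

    2a = |G_BB − G_bb| (homozygote difference), d = G_Bb − (G_BB+G_bb)/2
    (heterozygote deviation), with the orientation chosen so that B labels
    the high-value homozygote (a > 0); |d/a| classifies the mode.
    """

    two_a: float
    d: float
    d_over_a: float
    std_effect: float      # 2a / s_p
    maf: float
    minor_allele: str
    additive_effect: float
    mode: str

    @staticmethod
    def classify(d_over_a: float) -> str:
        ratio = abs(d_over_a)
        if ratio <= 0.5:
            return ADDITIVE
        if ratio < 1.25:
            return DOMINANT
        return OVERDOMINANT


def gene_action_from_effects(two_a: float, d: float) -> tuple[float, str]:
    """(d/a, mode) recomputed from homozygote difference 2a and heterozygote
    deviation d (a = 2a/2); the published decomposition's arithmetic."""
    if two_a < 0:
        raise AssociationError("2a must be non-negative")
    a = two_a / 2.0
    if a == 0:
        d_over_a = float("inf") * np.sign(d) if d else 0.0
    else:
        d_over_a = d / a
    return float(d_over_a), GeneActionRecord.classify(d_over_a)


def gene_action(
    g_BB: float,
    g_Bb: float,
    g_bb: float,
    minor_freq: float,
    trait_sd: float,
    overall_mean: float,
    minor_allele: str = "?",
    additive_formula: str = "as_printed",
) -> GeneActionRecord:
    """Gene-action record from genotype-class trait means.

    ``g_BB`` is the minor-allele homozygote class mean, ``g_Bb`` the
    heterozygote and ``g_bb`` the major-allele homozygote (B = minor allele,
    the convention of the published decomposition).  2a and d are
    orientation-free; d/a is reported with a > 0.  ``additive_formula``
    selects the published formula a = p_B·G_BB + p_b·G_Bb − G
    (``as_printed``; note it omits the bb class) or a genotype-frequency-
    weighted variant (``corrected``:
    a = p_B²·G_BB + 2p_Bp_b·G_Bb + p_b²·G_bb − G).
    """
    if trait_sd <= 0:
        raise AssociationError("trait standard deviation must be positive")
    for v in (g_BB, g_Bb, g_bb):
        if not np.isfinite(v):
            raise AssociationError("all three genotype class means required")
    two_a = abs(g_BB - g_bb)
    d = g_Bb - 0.5 * (g_BB + g_bb)
    d_over_a, mode = gene_action_from_effects(two_a, d)
    p_minor = minor_freq
    p_major = 1.0 - p_minor
    if additive_formula == "as_printed":
        additive = p_minor * g_BB + p_major * g_Bb - overall_mean
    elif additive_formula == "corrected":
        additive = (p_minor ** 2 * g_BB + 2 * p_minor * p_major * g_Bb
                    + p_major ** 2 * g_bb - overall_mean)
    else:
        raise AssociationError(f"unknown additive_formula {additive_formula!r}")
    return GeneActionRecord(
        two_a=float(two_a), d=float(d), d_over_a=d_over_a,
        std_effect=float(two_a / trait_sd), maf=float(minor_freq),
        minor_allele=minor_allele, additive_effect=float(additive),
        mode=mode,
    )


def gene_action_from_data(
    y: np.ndarray, marker: np.ndarray, minor_allele: str = "?",
    additive_formula: str = "as_printed",
) -> GeneActionRecord | None:
    """Gene-action record from raw trait values and dosages (0/1/2).

    Returns None (with a warning) when a genotype class is unobserved.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(marker, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    means = {}
    for dose in (0, 1, 2):
        sel = g == dose
        if not sel.any():
            warnings.warn(f"genotype class {dose} unobserved; mode undefined")
            return None
        means[dose] = float(y[sel].mean())
    p_counted = float(g.mean() / 2.0)
    maf = min(p_counted, 1 - p_counted)
    # dosage counts the minor allele, so dose 2 is the minor homozygote
    return gene_action(
        g_BB=means[2], g_Bb=means[1], g_bb=means[0],
        minor_freq=maf, trait_sd=float(y.std(ddof=1)),
        overall_mean=float(y.mean()), minor_allele=minor_allele,
        additive_formula=additive_formula,
    )


# ---------------------------------------------------------------------------
# validation-population tests
# ---------------------------------------------------------------------------

def mendelian_expected_ratio(parent1: float, parent2: float) -> dict[int, float] | None:
    """Expected progeny genotype proportions for a biallelic cross, or None
    when both parents are identically homozygous (monomorphic progeny)."""
    if np.isnan(parent1) or np.isnan(parent2):
        return None
    if parent1 == parent2 and parent1 in (0.0, 2.0):
        return None  # identically homozygous parents: monomorphic progeny
    gametes = {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}
    probs: dict[int, float] = {}
    for a1, q1 in gametes[int(parent1)].items():
        for a2, q2 in gametes[int(parent2)].items():
            probs[a1 + a2] = probs.get(a1 + a2, 0.0) + q1 * q2
    return probs


def mendelian_test(
    progeny: np.ndarray, parent1: float, parent2: float, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Pearson χ² test of progeny genotype counts against the Mendelian
    expectation of the cross; returns (chi2, p, keep) with keep = p ≥ alpha."""
    expected = mendelian_expected_ratio(parent1, parent2)
    if expected is None:
        raise AssociationError("cross is monomorphic or parents ungenotyped")
    g = np.asarray(progeny, dtype=float)
    g = g[np.isfinite(g)]
    n = len(g)
    classes = sorted(expected)
    obs = np.array([(g == c).sum() for c in classes], dtype=float)
    if len(classes) == 1:
        # e.g. AA × aa: all progeny heterozygous; any other genotype is a
        # Mendelian violation
        violated = obs[0] < n
        chi2 = float("inf") if violated else 0.0
        p = 0.0 if violated else 1.0
        return chi2, p, p >= alpha
    exp = np.array([expected[c] * n for c in classes])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=len(classes) - 1))
    return chi2, p, p >= alpha


def single_marker_anova(y: np.ndarray, marker: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a trait over genotype classes.

    Returns (p, r2_explained) where r2_explained = 100·SS_marker/SS_total.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(marker, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    classes = np.unique(g)
    if len(classes) < 2:
        raise AssociationError("need ≥2 genotype classes")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    for c in classes:
        yc = y[g == c]
        ss_between += len(yc) * (yc.mean() - grand) ** 2
    df_b = len(classes) - 1
    df_w = len(y) - len(classes)
    ss_within = ss_total - ss_between
    if df_w <= 0 or ss_within <= 0:
        return 0.0 if ss_between > 0 else 1.0, 100.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    r2 = 100.0 * ss_between / ss_total if ss_total > 0 else 0.0
    return p, r2


# ---------------------------------------------------------------------------
# discovery-population scan
# ---------------------------------------------------------------------------

def association_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    Q: np.ndarray | None = None,
    K: np.ndarray | None = None,
    maf_min: float = 0.10,
    fdr_threshold: float = 0.10,
    fdr_family: str = "trait",
    pi0: float | None = None,
    additive_formula: str = "as_printed",
) -> pd.DataFrame:
    """Q+K mixed-model scan of every common SNP against every trait.

    SNPs are filtered to minor-allele frequency > ``maf_min``; each (SNP,
    trait) pair is tested with the REML mixed model; Storey q-values are
    attached per trait family (or globally with ``fdr_family='global'``);
    pairs with q below ``fdr_threshold`` are flagged significant and given a
    gene-action record.  Phenotype rows must be indexed by individual ID
    matching ``genotypes.individuals``.
    """
    ids = list(genotypes.individuals)
    missing = [i for i in ids if i not in phenotypes.index]
    if missing:
        raise AssociationError(
            f"individuals missing from phenotype table: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    if fdr_family not in {"trait", "global"}:
        raise AssociationError("fdr_family must be 'trait' or 'global'")
    pheno = phenotypes.loc[ids]
    common = genotypes.filter_common(maf_min)
    eig = KinshipEigen.from_kinship(K) if K is not None else None

    rows = []
    for trait in pheno.columns:
        y = pheno[trait].to_numpy(dtype=float)
        for j, snp in enumerate(common.snp_ids):
            marker = common.dosages[:, j]
            try:
                fit: MLMFit = mlm_single_marker(y, marker, Q=Q, eig=eig)
            except MLMError as exc:
                warnings.warn(f"{snp}/{trait}: {exc}")
                continue
            rows.append({
                "snp_id": snp, "trait": trait,
                "position": int(common.positions[j]),
                "beta_marker": fit.beta_marker, "p_value": fit.p_value,
                "r2_explained": fit.r2_explained, "n_used": fit.n_used,
            })
    results = pd.DataFrame(rows)
    if results.empty:
        return results

    if fdr_family == "trait":
        results["q_value"] = np.nan
        for trait, idx in results.groupby("trait").groups.items():
            results.loc[idx, "q_value"] = storey_qvalues(
                results.loc[idx, "p_value"].to_numpy(), pi0=pi0)
    else:
        results["q_value"] = storey_qvalues(
            results["p_value"].to_numpy(), pi0=pi0)
    results["significant"] = results["q_value"] < fdr_threshold

    # gene-action decomposition for significant pairs
    for col in ("two_a", "d", "d_over_a", "std_effect", "maf",
                "additive_effect"):
        results[col] = np.nan
    results["mode"] = ""
    for k, row in results[results["significant"]].iterrows():
        y = pheno[row["trait"]].to_numpy(dtype=float)
        marker = common.column(row["snp_id"])
        rec = gene_action_from_data(y, marker,
                                    additive_formula=additive_formula)
        if rec is None:
            continue
        results.loc[k, ["two_a", "d", "d_over_a", "std_effect", "maf",
                        "additive_effect"]] = [
            rec.two_a, rec.d, rec.d_over_a, rec.std_effect, rec.maf,
            rec.additive_effect]
        results.loc[k, "mode"] = rec.mode
    return results


def validate_panel(
    progeny: GenotypeMatrix,
    parent1: np.ndarray,
    parent2: np.ndarray,
    phenotypes: pd.DataFrame,
    mendelian_alpha: float = 0.01,
    fdr_threshold: float = 0.10,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Validation-population confirmation of a marker panel.

    Each locus is first screened for Mendelian segregation (χ² at
    ``mendelian_alpha``); loci that pass are tested against each trait with
    a single-marker fixed-effects ANOVA, followed by Storey FDR per trait.
    """
    rows = []
    for j, snp in enumerate(progeny.snp_ids):
        try:
            chi2, p_mendel, keep = mendelian_test(
                progeny.dosages[:, j], parent1[j], parent2[j],
                alpha=mendelian_alpha)
        except AssociationError as exc:
            warnings.warn(f"{snp}: {exc}; locus skipped")
            continue
        rows.append({"snp_id": snp, "chi2": chi2, "p_mendelian": p_mendel,
                     "keep": keep})
    screen = pd.DataFrame(rows)
    if screen.empty:
        return screen

    ids = list(progeny.individuals)
    pheno = phenotypes.loc[ids]
    assoc_rows = []
    for snp in screen[screen["keep"]]["snp_id"]:
        marker = progeny.column(snp)
        for trait in pheno.columns:
            y = pheno[trait].to_numpy(dtype=float)
            try:
                p, r2 = single_marker_anova(y, marker)
            except AssociationError:
                continue
            assoc_rows.append({"snp_id": snp, "trait": trait, "p_value": p,
                               "r2_explained": r2})
    assoc = pd.DataFrame(assoc_rows)
    if not assoc.empty:
        assoc["q_value"] = np.nan
        for trait, idx in assoc.groupby("trait").groups.items():
            assoc.loc[idx, "q_value"] = storey_qvalues(
                assoc.loc[idx, "p_value"].to_numpy(), pi0=pi0)
        assoc["significant"] = assoc["q_value"] < fdr_threshold
        out = screen.merge(assoc, on="snp_id", how="left")
    else:
        out = screen
    return out
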