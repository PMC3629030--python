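"""Nucleotide-polymorphism statistics: segregating sites, π, Watterson's θ,
SNP frequency, and a per-region diversity table with synonymous /
nonsynonymous partitions.

Conventions
-----------
Columns containing a gap character and columns with more than two alleles are
excluded from every statistic, and the per-site denominators exclude the same
columns.  Singleton variants count as segregating (no frequency filter at this
stage).  π is the mean per-site pairwise difference proportion; θw is
S / (a_{n-1} · L_usable) with a_{n-1} the harmonic number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignmentSet
from .annotation import (
    SiteClassification,
    classify_alignment_sites,
    per_base_synonymous_fractions,
)
from .genemodel import GeneModel, _EXON_RE


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class DiversitySummary:
    """Polymorphism summary for one gene region (or site-class partition)."""

    region: str
    length_bp: float
    S: int
    percent_polymorphism: float
    pi: float
    theta_w: float
    n_sequences: int


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


def _interval(region) -> tuple[int, int] | None:
    if region is None:
        return None
    if hasattr(region, "start") and hasattr(region, "end"):
        return int(region.start), int(region.end)
    start, end = region
    return int(start), int(end)


def usable_columns(alignment: AlignmentSet) -> np.ndarray:
    """Mask of columns used for all statistics: gap-free and ≤ 2 alleles."""
    return (~alignment.has_gap()) & (alignment.n_alleles() <= 2)


def _column_mask(alignment: AlignmentSet, region) -> np.ndarray:
    mask = usable_columns(alignment)
    iv = _interval(region)
    if iv is not None:
        sel = np.zeros(alignment.length, dtype=bool)
        sel[iv[0]: iv[1]] = True
        mask &= sel
    return mask


def _pair_diff_weights(alignment: AlignmentSet) -> np.ndarray:
    """Per-column count of pairwise differences among sequences.

    For a biallelic gap-free column with allele counts (n1, n2) this equals
    n1*n2; monomorphic columns contribute 0.
    """
    n = alignment.n_sequences
    diffs = np.zeros(alignment.length)
    counts = np.zeros((4, alignment.length), dtype=int)
    for k, b in enumerate((b"A", b"C", b"G", b"T")):
        counts[k] = (alignment.matrix == b).sum(axis=0)
    # pairwise differences = (n_tot^2 - sum n_b^2) / 2 over non-gap bases
    n_tot = counts.sum(axis=0)
    diffs = (n_tot.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=0)) / 2.0
    return diffs


def segregating_sites(alignment: AlignmentSet, region=None) -> int:
    """Number of usable (gap-free, biallelic) segregating columns in region."""
    if alignment.n_sequences < 2:
        raise DiversityError("need at least 2 sequences")
    mask = _column_mask(alignment, region)
    return int(((alignment.n_alleles() == 2) & mask).sum())


def nucleotide_diversity_pi(alignment: AlignmentSet, region=None) -> float:
    """Average pairwise per-site difference proportion over usable columns."""
    n = alignment.n_sequences
    if n < 2:
        raise DiversityError("need at least 2 sequences")
    mask = _column_mask(alignment, region)
    L = int(mask.sum())
    if L == 0:
        return float("nan")
    diffs = _pair_diff_weights(alignment)[mask].sum()
    n_pairs = n * (n - 1) / 2.0
    return float(diffs / (n_pairs * L))


def watterson_theta(alignment: AlignmentSet, region=None) -> float:
    """θw = S / (a_{n-1} · L_usable) per site."""
    n = alignment.n_sequences
    if n < 2:
        raise DiversityError("need at least 2 sequences")
    mask = _column_mask(alignment, region)
    L = int(mask.sum())
    if L == 0:
        return float("nan")
    S = segregating_sites(alignment, region)
    return float(S / (harmonic_number(n - 1) * L))


def snp_frequency(length_bp: float, S: int) -> int | None:
    """bp per SNP: round(length/S) half away from zero; None when S = 0."""
    if S < 0:
        raise DiversityError("S must be non-negative")
    if S == 0:
        return None
    x = length_bp / S
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_polymorphism(length_bp: float, S: int) -> float:
    """100·S/length, the Table-style percentage-polymorphism column."""
    if length_bp <= 0:
        raise DiversityError("length must be positive")
    return 100.0 * S / length_bp


# ---------------------------------------------------------------------------
# full per-region table
# ---------------------------------------------------------------------------

def _partition_stats(
    alignment: AlignmentSet,
    cols: np.ndarray,
    site_length: float,
    label: str,
) -> DiversitySummary:
    """Summary for a site-class partition given its columns and site count."""
    n = alignment.n_sequences
    n_pairs = n * (n - 1) / 2.0
    S = int(len(cols))
    if site_length > 0:
        diffs = _pair_diff_weights(alignment)[cols].sum() if S else 0.0
        pi = float(diffs / (n_pairs * site_length))
        theta = float(S / (harmonic_number(n - 1) * site_length))
        pct = 100.0 * S / site_length
    else:
        pi = theta = pct = float("nan")
    return DiversitySummary(label, float(site_length), S, pct, pi, theta, n)


def diversity_table(
    alignment: AlignmentSet,
    model: GeneModel,
    classifications: list[SiteClassification] | None = None,
) -> pd.DataFrame:
    """Per-region diversity table with synonymous/nonsynonymous partitions.

    Rows: one per UTR/exon/intron in gene order, with ``synonymous`` and
    ``non_synonymous`` sub-rows per exon (fractional Nei–Gojobori site
    denominators), followed by ``total_silent`` (noncoding plus synonymous),
    gene-wide ``synonymous`` / ``non_synonymous`` aggregates, and ``total``.
    Columns: region, partition, length_bp, S, percent_polymorphism, pi,
    theta_w, bp_per_snp.
    """
    if classifications is None:
        classifications = classify_alignment_sites(alignment, model)
    n = alignment.n_sequences
    mask = usable_columns(alignment)
    seg = (alignment.n_alleles() == 2) & mask

    # per-base synonymous fractions on the gene coordinate system
    consensus = alignment.consensus().decode()
    cds_pos = np.array(model.cds_positions(), dtype=int)
    syn_frac_gene = np.full(model.total_length, np.nan)
    if len(cds_pos):
        cds_seq = "".join(consensus[p] for p in cds_pos)
        fr = per_base_synonymous_fractions(cds_seq, on_internal_stop="exclude")
        syn_frac_gene[cds_pos] = fr
        # excluded alignment columns carry no countable sites
        syn_frac_gene[~mask] = np.nan

    effect_by_pos = {c.position: c.coding_effect for c in classifications}

    # exon segregating columns with no classification (e.g. codon context
    # broken by gap columns) are excluded from all counts, like indel codons
    if len(cds_pos):
        cds_set = set(int(p) for p in cds_pos)
        for j in np.flatnonzero(seg):
            if int(j) in cds_set and int(j) not in effect_by_pos:
                seg[j] = False

    rows: list[dict] = []

    def add(summary: DiversitySummary, region: str, partition: str) -> None:
        rows.append({
            "region": region,
            "partition": partition,
            "length_bp": summary.length_bp,
            "S": summary.S,
            "percent_polymorphism": round(summary.percent_polymorphism, 2)
            if np.isfinite(summary.percent_polymorphism) else np.nan,
            "pi": round(summary.pi, 5) if np.isfinite(summary.pi) else np.nan,
            "theta_w": round(summary.theta_w, 5)
            if np.isfinite(summary.theta_w) else np.nan,
            "bp_per_snp": snp_frequency(summary.length_bp, summary.S)
            if summary.S else np.nan,
        })

    n_pairs = n * (n - 1) / 2.0

    for reg in model.regions:
        cols = np.flatnonzero(seg[reg.start:reg.end]) + reg.start
        L_use = float(mask[reg.start:reg.end].sum())
        add(_partition_stats(alignment, cols, L_use, reg.label),
            reg.label, "all")
        if _EXON_RE.match(reg.label):
            frac = syn_frac_gene[reg.start:reg.end]
            syn_len = float(np.nansum(frac))
            valid = float(np.sum(~np.isnan(frac)))
            nonsyn_len = valid - syn_len
            syn_cols = [c for c in cols
                        if effect_by_pos.get(int(c)) == "synonymous"]
            nonsyn_cols = [c for c in cols
                           if effect_by_pos.get(int(c)) in ("missense", "nonsense")]
            add(_partition_stats(alignment, np.array(syn_cols, dtype=int),
                                 syn_len, reg.label), reg.label, "synonymous")
            add(_partition_stats(alignment, np.array(nonsyn_cols, dtype=int),
                                 nonsyn_len, reg.label), reg.label,
                "non_synonymous")

    df = pd.DataFrame(rows)

    # gene-wide aggregates ---------------------------------------------------
    all_cols = np.flatnonzero(seg)
    syn_cols_all = np.array(
        [p for p, e in effect_by_pos.items() if e == "synonymous"], dtype=int)
    nonsyn_cols_all = np.array(
        [p for p, e in effect_by_pos.items() if e in ("missense", "nonsense")],
        dtype=int)
    noncoding_cols = np.array(
        [p for p, e in effect_by_pos.items() if e == "noncoding"], dtype=int)

    syn_len_all = float(np.nansum(syn_frac_gene))
    cds_valid = float(np.sum(~np.isnan(syn_frac_gene)))
    nonsyn_len_all = cds_valid - syn_len_all
    L_use_total = float(mask.sum())
    noncoding_len = L_use_total - cds_valid
    silent_cols = np.concatenate([noncoding_cols, syn_cols_all]) \
        if len(noncoding_cols) or len(syn_cols_all) else np.array([], dtype=int)

    agg = [
        (_partition_stats(alignment, silent_cols,
                          noncoding_len + syn_len_all, "total_silent"),
         "total_silent", "all"),
        (_partition_stats(alignment, syn_cols_all, syn_len_all, "synonymous"),
         "total_silent", "synonymous"),
        (_partition_stats(alignment, nonsyn_cols_all, nonsyn_len_all,
                          "non_synonymous"), "total_silent", "non_synonymous"),
        (_partition_stats(alignment, all_cols, L_use_total, "total"),
         "total", "all"),
    ]
    for summary, region, partition in agg:
        add(summary, region, partition)

    return pd.DataFrame(rows)


def diversity_totals(table: pd.DataFrame) -> dict:
    """One-line gene-total summary (π, θw, S, π_nonsyn/π_syn ratio)."""
    tot = table[(table.region == "total") & (table.partition == "all")].iloc[0]
    syn = table[(table.region == "total_silent")
                & (table.partition == "synonymous")].iloc[0]
    nonsyn = table[(table.region == "total_silent")
                   & (table.partition == "non_synonymous")].iloc[0]
    ratio = (nonsyn.pi / syn.pi) if syn.pi and np.isfinite(syn.pi) else np.nan
    return {
        "S_total": int(tot.S),
        "pi_total": float(tot.pi),
        "theta_w_total": float(tot.theta_w),
        "percent_polymorphism": float(tot.percent_polymorphism),
        "bp_per_snp": None if pd.isna(tot.bp_per_snp) else int(tot.bp_per_snp),
        "S_synonymous": int(syn.S),
        "S_nonsynonymous": int(nonsyn.S),
        "pi_nonsyn_over_pi_syn": float(ratio) if np.isfinite(ratio) else None,
    }
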