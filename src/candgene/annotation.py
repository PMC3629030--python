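"""Variant-site annotation: region assignment, coding-effect classification
and Nei–Gojobori fractional synonymous/nonsynonymous site counting.

The Nei–Gojobori convention counts, for each codon position, the fraction of
the three possible single-base changes that preserve the encoded amino acid
as synonymous "sites"; changes creating a stop codon count as nonsynonymous.
Synonymous plus nonsynonymous sites therefore partition the coding length
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .alignment import AlignmentSet, GAP
from .genemodel import GeneModel, _EXON_RE

BASES = ("A", "C", "G", "T")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for the three stop codons (standard code)
CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_AA.update({c: "*" for c in _TABLE.stop_codons})

NONCODING = "noncoding"
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteClassification:
    """Classification of one segregating alignment column."""

    position: int
    region: str
    coding_effect: str          # noncoding / synonymous / missense / nonsense
    codon: str | None = None    # reference (consensus-context) codon
    alt_codon: str | None = None

    @property
    def is_nonsynonymous(self) -> bool:
        return self.coding_effect in (MISSENSE, NONSENSE)


@dataclass(frozen=True)
class SiteCounts:
    """Fractional Nei–Gojobori site counts for a coding region."""

    synonymous_sites: float
    nonsynonymous_sites: float
    region: str = "cds"

    @property
    def total(self) -> float:
        return self.synonymous_sites + self.nonsynonymous_sites


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_AA:
        raise AnnotationError(f"ambiguous or invalid codon {codon!r}")
    return CODON_AA[codon]


def classify_coding_change(ref_codon: str, alt_codon: str) -> str:
    """Classify a single-base codon change as synonymous/missense/nonsense."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise AnnotationError("codons must be 3-mers")
    ndiff = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if ndiff != 1:
        raise AnnotationError(
            f"codons {ref_codon}->{alt_codon} differ at {ndiff} positions, expected 1"
        )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == "*":
        raise AnnotationError("reference codon is a stop codon")
    if alt_aa == "*":
        return NONSENSE
    return SYNONYMOUS if alt_aa == ref_aa else MISSENSE


def position_synonymous_fraction(codon: str, within: int) -> float:
    """Fraction (of 3) of single-base changes at ``codon[within]`` that are
    synonymous; stop-creating changes count as nonsynonymous."""
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise AnnotationError("stop codon has no site fractions")
    syn = 0
    for b in BASES:
        if b == codon[within]:
            continue
        alt = codon[:within] + b + codon[within + 1:]
        if translate_codon(alt) == aa:
            syn += 1
    return syn / 3.0


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Enumerates all 9 single-base changes; a change is synonymous iff the
    amino acid is preserved (stop-creating changes are nonsynonymous).
    """
    syn = sum(position_synonymous_fraction(codon, k) for k in range(3))
    return syn, 3.0 - syn


def per_base_synonymous_fractions(
    coding_sequence: str, on_internal_stop: str = "raise"
) -> np.ndarray:
    """Per-base synonymous site fractions over an in-frame CDS.

    Returns an array of length ``len(coding_sequence)`` whose k-th entry is
    the synonymous fraction of base k under Nei–Gojobori counting, or NaN for
    bases in excluded codons (codons containing gap/ambiguous characters, and
    a trailing stop codon).  An internal stop codon raises, or is excluded
    when ``on_internal_stop='exclude'``.
    """
    seq = coding_sequence.upper()
    if len(seq) % 3 != 0:
        raise AnnotationError(f"CDS length {len(seq)} not divisible by 3")
    n_codons = len(seq) // 3
    out = np.full(len(seq), np.nan)
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        if any(b not in "ACGT" for b in codon):
            continue  # gap/ambiguity: codon excluded
        if translate_codon(codon) == "*":
            if i == n_codons - 1 or on_internal_stop == "exclude":
                continue  # stop codon carries no countable sites
            raise AnnotationError(f"internal stop codon at codon index {i}")
        for k in range(3):
            out[3 * i + k] = position_synonymous_fraction(codon, k)
    return out


def count_syn_nonsyn_sites(coding_sequence: str, region: str = "cds") -> SiteCounts:
    """Nei–Gojobori fractional site counts over a CDS.

    The length must be a multiple of 3; excluded codons (gaps, trailing stop)
    contribute no sites, so synonymous + nonsynonymous sites equal the counted
    (non-excluded) coding length.
    """
    frac = per_base_synonymous_fractions(coding_sequence)
    valid = ~np.isnan(frac)
    syn = float(np.nansum(frac))
    return SiteCounts(syn, float(valid.sum()) - syn, region=region)


def classify_alignment_sites(
    alignment: AlignmentSet, model: GeneModel
) -> list[SiteClassification]:
    """Classify every usable biallelic segregating column of the alignment.

    Columns containing a gap character are excluded (indel regions are left
    out of all polymorphism counts); columns with more than two alleles are
    excluded with a ``multiallelic`` marker in the returned warnings list on
    the module logger.  Codon context is taken from the majority consensus.
    """
    if alignment.length != model.total_length:
        raise AnnotationError(
            f"alignment length {alignment.length} != gene length {model.total_length}"
        )
    gap_cols = alignment.has_gap()
    n_alleles = alignment.n_alleles()
    consensus = alignment.consensus().decode()
    cds_pos = model.cds_positions()
    cds_seq = "".join(consensus[p] for p in cds_pos)
    out: list[SiteClassification] = []
    for j in np.flatnonzero(n_alleles >= 2):
        if gap_cols[j] or n_alleles[j] > 2:
            continue  # excluded: gap or multiallelic column
        region = model.assign_region(int(j))
        if not _EXON_RE.match(region):
            out.append(SiteClassification(int(j), region, NONCODING))
            continue
        cds_idx = model.cds_index_of(int(j))
        if cds_idx is None:
            out.append(SiteClassification(int(j), region, NONCODING))
            continue
        codon_idx, within = divmod(cds_idx, 3)
        ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
        alleles = sorted(alignment.allele_counts(int(j)))
        ref_base = consensus[j].encode()
        alt_base = next(a for a in alleles if a != ref_base)
        alt_codon = (
            ref_codon[:within] + alt_base.decode() + ref_codon[within + 1:]
        )
        if "-" in ref_codon or "-" in alt_codon:
            continue
        if translate_codon(ref_codon) == "*":
            # stop-codon context: stop-retaining changes are synonymous,
            # stop-loss changes alter the protein (pooled with missense)
            effect = SYNONYMOUS if translate_codon(alt_codon) == "*" \
                else MISSENSE
        else:
            effect = classify_coding_change(ref_codon, alt_codon)
        out.append(SiteClassification(int(j), region, effect, ref_codon, alt_codon))
    return out
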