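"""Published summary data for the PtUXS1 candidate-gene study.

These are printed summary statistics from the published association-genetics
study of the *Populus tomentosa* UDP-glucuronate decarboxylase gene *PtUXS1*
(a 4374-bp gene resequenced in 44 unrelated individuals; 82 common SNPs
genotyped in a 426-individual association panel).  They serve as inputs for
worked examples and for desk-scale recomputation of derived quantities
(SNP frequencies, gene-action modes); they are not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

from .genemodel import GeneModel, gene_model_from_lengths

#: Region layout of the PtUXS1 gene: 133 bp 5'UTR, 7 exons (1293 bp CDS),
#: 6 introns (2574 bp), 374 bp 3'UTR; total 4374 bp.
PTUXS1_LAYOUT: tuple[tuple[str, int], ...] = (
    ("five_prime_utr", 133),
    ("exon_1", 609),
    ("intron_1", 135),
    ("exon_2", 145),
    ("intron_2", 88),
    ("exon_3", 80),
    ("intron_3", 1676),
    ("exon_4", 84),
    ("intron_4", 120),
    ("exon_5", 75),
    ("intron_5", 327),
    ("exon_6", 93),
    ("intron_6", 228),
    ("exon_7", 207),
    ("three_prime_utr", 374),
)


def ptuxs1_gene_model() -> GeneModel:
    """The PtUXS1 gene model (coding frame starts at the first exon base)."""
    return gene_model_from_lengths(PTUXS1_LAYOUT, coding_offset=0, name="PtUXS1")


#: Published per-region polymorphism counts for PtUXS1: region length in bp
#: and number of segregating sites (indel-containing regions excluded).
PTUXS1_POLYMORPHISM = pd.DataFrame(
    [
        ("five_prime_utr", 133, 7),
        ("exon_1", 609, 29),
        ("intron_1", 135, 5),
        ("exon_2", 145, 5),
        ("intron_2", 88, 7),
        ("exon_3", 80, 3),
        ("intron_3", 1676, 84),
        ("exon_4", 84, 6),
        ("intron_4", 120, 17),
        ("exon_5", 75, 4),
        ("intron_5", 327, 19),
        ("exon_6", 93, 2),
        ("intron_6", 228, 17),
        ("exon_7", 207, 13),
        ("three_prime_utr", 374, 25),
    ],
    columns=["region", "length_bp", "S"],
)

#: Published exon-wide diversity at synonymous vs nonsynonymous sites.
PTUXS1_CODING_DIVERSITY = {
    "pi_synonymous": 0.02210,
    "pi_nonsynonymous": 0.00385,
    "S_synonymous": 28,
    "S_nonsynonymous": 34,
}

#: Published total SNP count and the number of genotyped common SNPs
#: (minor allele frequency > 0.10).
PTUXS1_SNP_COUNTS = {"total": 243, "common": 82, "silent": 209}

#: Published marker-effect estimates for the nine significant marker-trait
#: associations in the 426-individual discovery panel.  2a is the absolute
#: difference between homozygote class means; d is the heterozygote deviation
#: from the homozygote midpoint (both in trait units).
PTUXS1_MARKER_EFFECTS = pd.DataFrame(
    [
        ("holocellulose", "SNP2", 1.1154, 0.0619),
        ("holocellulose", "SNP22", 1.7470, 3.2853),
        ("alpha_cellulose", "SNP10", 1.3871, 0.3247),
        ("fiber_length", "SNP27", 0.0758, 0.0240),
        ("fiber_length", "SNP56", 0.0172, 0.0095),
        ("fiber_width", "SNP6", 1.7748, 0.9877),
        ("microfibril_angle", "SNP68", 1.6288, 0.8427),
        ("diameter", "SNP6", 1.7632, 1.0698),
        ("stem_volume", "SNP6", 0.0715, -0.0228),
    ],
    columns=["trait", "snp", "two_a", "d"],
)
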