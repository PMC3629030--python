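"""Generate a full synthetic candidate-gene study and look at its parts.

The generator emulates the design of a poplar candidate-gene association
study: 88 haplotype sequences of a 4.4-kb gene, 82 common SNPs genotyped in
426 individuals from 3 geographic subpopulations, 10 quantitative traits
with planted marker effects plus a polygenic background, and a 1200-progeny
F1 validation cross.
"""

from candgene import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1))

aln = study["alignment"]
gm = study["genotypes"]
print(f"alignment: {aln.n_sequences} haplotypes x {aln.length} bp")
print(f"panel:     {gm.n_individuals} individuals x {gm.n_snps} SNPs, "
      f"min MAF {gm.maf().min():.3f}")
print(f"traits:    {study['phenotypes'].shape[1]} quantitative traits")
print(f"progeny:   {study['progeny'].n_individuals} F1 individuals")
print("\nplanted marker effects (the truth the scan should recover):")
print(study["truth"].to_string(index=False))
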