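"""Sliding-window haplotype trend regression.

Haplotype frequencies over 3-SNP windows are estimated by EM from unphased
genotypes; each trait is regressed on the posterior expected haplotype
dosages and window significance comes from 1000 trait permutations.
"""

from candgene import SimulationConfig, simulate_study, sliding_scan

study = simulate_study(SimulationConfig(seed=1))
truth = study["truth"].iloc[2]          # a planted additive QTL
trait = truth.trait

scan = sliding_scan(
    study["genotypes"].filter_common(0.10),
    study["phenotypes"][[trait]],
    window=3, freq_min=0.01, n_permutations=1000, seed=1,
)
print(f"{len(scan)} windows tested for {trait} "
      f"(planted causal SNP: {truth.snp_id})")
top = scan.nsmallest(5, "p_perm")
print(top[["window_snps", "p_perm", "r2_explained",
           "significant_haplotypes"]].to_string(index=False))
print("\nWindows spanning the causal SNP should carry the smallest "
      "permutation p-values; listed haplotypes pass the 1% frequency "
      "filter and are individually associated at p ≤ 0.05.")
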