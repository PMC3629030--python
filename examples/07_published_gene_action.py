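"""Gene-action modes of the published PtUXS1 marker-trait associations.

Recomputes d/a from the published homozygote difference (2a) and
heterozygote deviation (d) of each of the nine significant associations and
classifies the mode of gene action: additive |d/a| ≤ 0.5, partial-to-full
dominance 0.5 < |d/a| < 1.25, over/underdominance |d/a| > 1.25.
"""

from candgene import gene_action_from_effects
from candgene.datasets import PTUXS1_MARKER_EFFECTS

rows = []
for r in PTUXS1_MARKER_EFFECTS.itertuples():
    ratio, mode = gene_action_from_effects(r.two_a, r.d)
    rows.append((r.trait, r.snp, r.two_a, r.d, round(ratio, 4), mode))
    print(f"{r.trait:18s} {r.snp:6s} 2a={r.two_a:7.4f} d={r.d:7.4f} "
          f"d/a={ratio:8.4f}  {mode}")

modes = [row[-1] for row in rows]
print(f"\n{modes.count('additive')} additive, {modes.count('dominant')} "
      f"dominant, {modes.count('overdominant')} overdominant — most marker "
      "effects on wood-property traits act with partial to full dominance.")
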