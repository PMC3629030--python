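"""End-to-end orchestration: simulate → annotate → diversity → LD →
association → haplotype → validation, with standard-format outputs.

Every stage writes a TSV artifact shaped like the corresponding published
summary (per-region diversity table; LD pairs/blocks/decay; discovery
associations with gene-action columns; haplotype trend-regression results
with single-marker cross-references; Mendelian-screened validation results),
plus a JSON run report with per-stage row counts and filter bookkeeping.
Outputs are deterministic given config + seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .annotation import classify_alignment_sites
from .association import association_scan, validate_panel
from .diversity import diversity_table, diversity_totals
from .haplotypes import sliding_scan
from .ld import detect_blocks, fit_ld_decay, pairwise_r2, LDError
from .simulate import SimulationConfig, simulate_study

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full pipeline run (defaults follow the
    published analysis settings)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    maf_min: float = 0.10
    fdr_threshold: float = 0.10
    block_r2: float = 0.75
    hap_freq_min: float = 0.01
    mendelian_alpha: float = 0.01
    significance_alpha: float = 0.05
    hap_window: int = 3
    hap_permutations: int = 1000
    ld_decay_r2_threshold: float = 0.1

    def validate(self) -> None:
        for name in ("maf_min", "fdr_threshold", "block_r2", "hap_freq_min",
                     "mendelian_alpha", "significance_alpha",
                     "ld_decay_r2_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.hap_window < 2:
            raise ValueError("hap_window must be ≥ 2")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis on a synthetic study and write all artifacts.

    Returns the run report (also written to ``run_report.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {},
                    "config": {
                        "seed": config.simulation.seed,
                        "maf_min": config.maf_min,
                        "fdr_threshold": config.fdr_threshold,
                        "block_r2": config.block_r2,
                        "hap_freq_min": config.hap_freq_min,
                        "mendelian_alpha": config.mendelian_alpha,
                        "significance_alpha": config.significance_alpha,
                    }}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
        return done

    # -- simulate ----------------------------------------------------------
    done = stage("simulate")
    study = simulate_study(config.simulation)
    genotypes, phenotypes = study["genotypes"], study["phenotypes"]
    study["alignment"].to_fasta(outdir / "alignment.fasta")
    config.simulation.gene_model.to_tsv(outdir / "gene_model.tsv")
    config.simulation.gene_model.to_gff3(outdir / "gene_model.gff3")
    cio.write_genotypes_tsv(genotypes, outdir / "genotypes.tsv",
                            outdir / "snp_map.tsv")
    cio.write_genotypes_vcf(genotypes, outdir / "genotypes.vcf")
    cio.write_phenotypes_tsv(phenotypes, outdir / "phenotypes.tsv")
    cio.write_q_matrix_tsv(study["Q"], list(genotypes.individuals),
                           outdir / "q_matrix.tsv")
    cio.write_kinship_tsv(study["K"], list(genotypes.individuals),
                          outdir / "kinship.tsv")
    study["truth"].to_csv(outdir / "truth_qtl.tsv", sep="\t", index=False)
    pd.DataFrame({"snp_id": genotypes.snp_ids,
                  "parent1": study["parent1"].astype(int),
                  "parent2": study["parent2"].astype(int)}
                 ).to_csv(outdir / "parents.tsv", sep="\t", index=False)
    done(individuals=genotypes.n_individuals, snps=genotypes.n_snps,
         haplotypes=study["alignment"].n_sequences)

    # -- diversity ---------------------------------------------------------
    done = stage("diversity")
    model = config.simulation.gene_model
    classifications = classify_alignment_sites(study["alignment"], model)
    div = diversity_table(study["alignment"], model, classifications)
    div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    totals = diversity_totals(div)
    (outdir / "diversity_totals.json").write_text(json.dumps(totals, indent=1))
    done(rows=len(div), segregating_sites=totals["S_total"])

    # -- LD ----------------------------------------------------------------
    done = stage("ld")
    r2_matrix, pairs = pairwise_r2(genotypes)
    pairs.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    blocks = detect_blocks(r2_matrix, threshold=config.block_r2)
    pd.DataFrame(
        [{"start_snp": genotypes.snp_ids[b.start_snp_index],
          "end_snp": genotypes.snp_ids[b.end_snp_index],
          "start_index": b.start_snp_index, "end_index": b.end_snp_index,
          "n_snps": b.size} for b in blocks]
    ).to_csv(outdir / "ld_blocks.tsv", sep="\t", index=False)
    try:
        decay = fit_ld_decay(pairs, n_sequences=2 * genotypes.n_individuals)
        decay_rows = {
            "ols_intercept": decay.ols_intercept,
            "ols_slope": decay.ols_slope,
            "hw_rho_per_bp": decay.hw_rho,
            "ols_distance_at_threshold": decay.distance_at_r2(
                config.ld_decay_r2_threshold, model="linear"),
            "hw_distance_at_threshold": decay.distance_at_r2(
                config.ld_decay_r2_threshold, model="hill_weir"),
        }
    except LDError:
        decay_rows = {}
    pd.DataFrame([decay_rows]).to_csv(outdir / "ld_decay.tsv", sep="\t",
                                      index=False)
    done(pairs=len(pairs), blocks=len(blocks))

    # -- association scan --------------------------------------------------
    done = stage("association")
    n_before = genotypes.n_snps
    assoc = association_scan(
        genotypes, phenotypes, Q=study["Q"], K=study["K"],
        maf_min=config.maf_min, fdr_threshold=config.fdr_threshold,
    )
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    n_common = assoc["snp_id"].nunique() if not assoc.empty else 0
    done(snps_before_maf_filter=n_before, snps_after_maf_filter=n_common,
         snps_removed=n_before - n_common,
         tests=len(assoc),
         significant=int(assoc["significant"].sum()) if not assoc.empty else 0)

    # -- haplotype trend regression ---------------------------------------
    done = stage("haplotype")
    common = genotypes.filter_common(config.maf_min)
    htr = sliding_scan(
        common, phenotypes, window=config.hap_window,
        freq_min=config.hap_freq_min,
        n_permutations=config.hap_permutations,
        seed=config.simulation.seed,
        significance_alpha=config.significance_alpha,
    )
    # cross-reference: best single-marker q-value among the window's SNPs
    if not htr.empty and not assoc.empty:
        best_q = []
        for _, row in htr.iterrows():
            snps = row["window_snps"].split("|")
            sub = assoc[(assoc["trait"] == row["trait"])
                        & assoc["snp_id"].isin(snps)]
            best_q.append(float(sub["q_value"].min()) if len(sub) else np.nan)
        htr["best_single_marker_q"] = best_q
    htr.to_csv(outdir / "haplotype_results.tsv", sep="\t", index=False)
    done(windows=htr["window_start"].nunique() if not htr.empty else 0,
         tests=len(htr),
         significant=int(htr["significant"].sum()) if not htr.empty else 0)

    # -- validation --------------------------------------------------------
    done = stage("validation")
    panel_snps = sorted(
        assoc[assoc["p_value"] < config.significance_alpha]["snp_id"].unique()
    ) if not assoc.empty else []
    progeny = study["progeny"]
    panel_idx = [progeny.snp_ids.index(s) for s in panel_snps
                 if s in progeny.snp_ids]
    if panel_idx:
        panel = progeny.subset_snps(panel_idx)
        validation = validate_panel(
            panel, study["parent1"][panel_idx], study["parent2"][panel_idx],
            study["progeny_phenotypes"],
            mendelian_alpha=config.mendelian_alpha,
            fdr_threshold=config.fdr_threshold,
        )
    else:
        validation = pd.DataFrame()
    validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    done(panel_snps=len(panel_idx),
         kept=int(validation.drop_duplicates("snp_id")["keep"].sum())
         if "keep" in validation.columns else 0)

    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
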