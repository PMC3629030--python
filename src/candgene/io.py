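"""File adapters: VCF v4.2 and TSV genotypes, phenotype/Q/kinship tables.

Genotype TSV dialect: an ``individual`` ID column plus one column per SNP
holding minor-allele dosages 0/1/2 with ``NA`` for missing; SNP positions
travel in a companion two-column map (``snp_id``, ``position``) or in the
VCF POS field.  Write-then-read round-trips preserve values exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError


# ---------------------------------------------------------------------------
# genotypes: TSV
# ---------------------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path,
                        map_path: str | Path | None = None) -> None:
    df = genotypes.to_frame()
    out = df.copy()
    out.insert(0, "individual", df.index)
    with np.errstate(invalid="ignore"):
        for c in df.columns:
            out[c] = out[c].map(
                lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)
    if map_path is not None:
        pd.DataFrame({"snp_id": genotypes.snp_ids,
                      "position": genotypes.positions}
                     ).to_csv(map_path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path,
                       map_path: str | Path | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "individual" not in df.columns:
        raise GenotypeError(f"{path}: missing 'individual' column")
    individuals = df["individual"].tolist()
    snp_ids = [c for c in df.columns if c != "individual"]
    dosages = np.full((len(individuals), len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        col = df[snp]
        for i, v in enumerate(col):
            if v == "NA" or pd.isna(v):
                continue
            try:
                dosages[i, j] = float(v)
            except ValueError as exc:
                raise GenotypeError(
                    f"{path}: bad dosage {v!r} at record {i + 2}") from exc
    positions = None
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t").set_index("snp_id")
        positions = np.array([int(mp.loc[s, "position"]) for s in snp_ids])
    return GenotypeMatrix(dosages, individuals, snp_ids, positions)


# ---------------------------------------------------------------------------
# genotypes: VCF v4.2
# ---------------------------------------------------------------------------

def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path,
                        chrom: str = "gene", ref: str = "A",
                        alt: str = "G") -> None:
    """Minimal VCF v4.2; the ALT allele is the counted (dosage) allele."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.individuals),
    ]
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, snp in enumerate(genotypes.snp_ids):
        pos = int(genotypes.positions[j])
        pos_1 = pos + 1 if pos >= 0 else j + 1
        calls = [
            "./." if np.isnan(v) else gt_of[v]
            for v in genotypes.dosages[:, j]
        ]
        lines.append(
            f"{chrom}\t{pos_1}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path: str | Path, orient: str = "alt") -> GenotypeMatrix:
    """Read a (plain-text) VCF into dosages of the counted allele.

    ``orient='alt'`` counts the ALT allele as written; ``orient='minor'``
    flips any SNP whose ALT-allele frequency exceeds 0.5 so the counted
    allele is the minor allele.
    """
    individuals: list[str] = []
    snp_ids, positions, rows = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise GenotypeError(f"{path}: malformed record at line {lineno}")
            _, pos, snp_id, _, alt, _, _, _, fmt = parts[:9]
            if "," in alt:
                raise GenotypeError(
                    f"{path}: multiallelic record at line {lineno}")
            gt_idx = fmt.split(":").index("GT")
            dosage_row = []
            for call in parts[9:]:
                gt = call.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    dosage_row.append(np.nan)
                else:
                    try:
                        dosage_row.append(
                            float(sum(int(a) for a in gt.split("/"))))
                    except ValueError as exc:
                        raise GenotypeError(
                            f"{path}: bad genotype {gt!r} at line {lineno}"
                        ) from exc
            snp_ids.append(snp_id)
            positions.append(int(pos) - 1)
            rows.append(dosage_row)
    if not individuals:
        raise GenotypeError(f"{path}: no #CHROM header line")
    dosages = np.array(rows, dtype=float).T
    gm = GenotypeMatrix(dosages, individuals, snp_ids, np.array(positions))
    if orient == "minor":
        flip = gm.allele_freq() > 0.5
        gm.dosages[:, flip] = 2.0 - gm.dosages[:, flip]
    elif orient != "alt":
        raise GenotypeError(f"unknown orientation {orient!r}")
    return gm


# ---------------------------------------------------------------------------
# phenotype / Q / kinship tables
# ---------------------------------------------------------------------------

def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="individual")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual",
                       float_precision="round_trip")


def write_q_matrix_tsv(Q: np.ndarray, individuals: list[str],
                       path: str | Path) -> None:
    df = pd.DataFrame(Q, index=individuals,
                      columns=[f"subpop_{k + 1}" for k in range(Q.shape[1])])
    df.to_csv(path, sep="\t", index_label="individual")


def read_q_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="individual",
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), df.index.tolist()


def write_kinship_tsv(K: np.ndarray, individuals: list[str],
                      path: str | Path) -> None:
    pd.DataFrame(K, index=individuals, columns=individuals).to_csv(
        path, sep="\t", index_label="individual")


def read_kinship_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="individual",
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), df.index.tolist()
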