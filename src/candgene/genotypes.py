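"""Diploid genotype matrices coded as minor-allele dosage (0/1/2, NaN missing)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals × biallelic SNPs, coded by counted-allele dosage.

    ``dosages`` is an (n_individuals, n_snps) float array with values in
    {0, 1, 2} and NaN for missing calls.  ``positions`` are base-pair
    coordinates on the gene coordinate system (``-1`` when unknown).
    """

    dosages: np.ndarray
    individuals: list[str]
    snp_ids: list[str]
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if len(self.individuals) != n:
            raise GenotypeError("individual count mismatch")
        if len(self.snp_ids) != m:
            raise GenotypeError("SNP id count mismatch")
        if self.positions is None:
            self.positions = np.full(m, -1, dtype=int)
        else:
            self.positions = np.asarray(self.positions, dtype=int)
            if self.positions.shape != (m,):
                raise GenotypeError("positions length mismatch")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise GenotypeError(
                f"invalid dosage {self.dosages[tuple(bad)]} at "
                f"individual {self.individuals[bad[0]]}, SNP {self.snp_ids[bad[1]]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP (missing-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def column(self, j: int | str) -> np.ndarray:
        if isinstance(j, str):
            j = self.snp_ids.index(j)
        return self.dosages[:, j]

    def subset_snps(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool \
            else np.asarray(mask, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.individuals),
            [self.snp_ids[i] for i in idx],
            self.positions[idx],
        )

    def filter_common(self, maf_min: float = 0.10) -> "GenotypeMatrix":
        """Keep SNPs with minor-allele frequency strictly above ``maf_min``."""
        return self.subset_snps(self.maf() > maf_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.individuals,
                            columns=self.snp_ids)
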