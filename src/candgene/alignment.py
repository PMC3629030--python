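"""Haplotype sequence alignments.

:class:`AlignmentSet` holds n haplotype sequences over L aligned columns as a
numpy byte matrix, with explicit handling of gap columns (which the diversity
statistics exclude, mirroring the convention of excluding indel-containing
regions from polymorphism counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = b"-"
VALID_BASES = frozenset(b"ACGT")


@dataclass
class AlignmentSet:
    """n aligned haplotype sequences of equal length.

    ``matrix`` is an (n, L) array of dtype ``S1`` holding uppercase bases
    (``A/C/G/T``) and ``-`` for alignment gaps.
    """

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("number of names must match number of sequences")

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    # -- column views ------------------------------------------------------

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def has_gap(self) -> np.ndarray:
        """Boolean mask over columns: any gap character present."""
        return (self.matrix == GAP).any(axis=0)

    def allele_counts(self, j: int) -> dict[bytes, int]:
        """Counts of non-gap bases in column j."""
        col = self.matrix[:, j]
        vals, counts = np.unique(col[col != GAP], return_counts=True)
        return {bytes(v): int(c) for v, c in zip(vals, counts)}

    def n_alleles(self) -> np.ndarray:
        """Number of distinct non-gap bases per column (vectorised)."""
        out = np.zeros(self.length, dtype=int)
        for b in (b"A", b"C", b"G", b"T"):
            out += (self.matrix == b).any(axis=0)
        return out

    def consensus(self) -> bytes:
        """Majority-rule consensus; ties broken by alphabetical base."""
        cons = bytearray()
        for j in range(self.length):
            counts = self.allele_counts(j)
            if not counts:
                cons += GAP
                continue
            best = max(sorted(counts), key=lambda b: counts[b])
            cons += best
        return bytes(cons)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentSet":
        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype="S1"))
        if not rows:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
        return cls(names, np.vstack(rows))

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(self.matrix[i].tobytes().decode()), id=name, description="")
            for i, name in enumerate(self.names)
        ]
        SeqIO.write(recs, str(path), "fasta")
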