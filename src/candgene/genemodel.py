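"""Gene models: ordered UTR/exon/intron region maps with reading frame.

A :class:`GeneModel` is a strand-aware partition of ``[0, total_length)`` into
contiguous, non-overlapping regions labelled ``five_prime_utr``, ``exon_k``,
``intron_k`` and ``three_prime_utr``.  Coordinates are 0-based half-open
internally; 1-based only at the GFF3 boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

FIVE_UTR = "five_prime_utr"
THREE_UTR = "three_prime_utr"

_EXON_RE = re.compile(r"^exon_(\d+)$")
_INTRON_RE = re.compile(r"^intron_(\d+)$")


class GeneModelError(ValueError):
    """Raised for inconsistent gene-model definitions."""


@dataclass(frozen=True)
class Region:
    label: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class GeneModel:
    """Ordered coordinate map of a gene's UTR/exon/intron structure.

    Parameters
    ----------
    regions
        Regions in genomic order, jointly covering ``[0, total_length)``
        without gaps or overlap.  Exon/intron labels must alternate.
    coding_offset
        Frame of the first exon base: number of leading exon bases to trim
        before the first complete codon (0, 1 or 2).
    strand
        ``+`` or ``-``; sequence coordinates are always given on the stored
        (sense) strand, so ``-`` is informational.
    """

    regions: tuple[Region, ...]
    coding_offset: int = 0
    strand: str = "+"
    name: str = "gene"

    def __post_init__(self) -> None:
        if not self.regions:
            raise GeneModelError("gene model needs at least one region")
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"invalid strand {self.strand!r}")
        if self.coding_offset not in {0, 1, 2}:
            raise GeneModelError("coding_offset must be 0, 1 or 2")
        pos = 0
        prev_kind = None
        for reg in self.regions:
            if reg.start != pos:
                raise GeneModelError(
                    f"region {reg.label} starts at {reg.start}, expected {pos}"
                )
            if reg.end <= reg.start:
                raise GeneModelError(f"region {reg.label} has non-positive length")
            m_ex, m_in = _EXON_RE.match(reg.label), _INTRON_RE.match(reg.label)
            if reg.label not in {FIVE_UTR, THREE_UTR} and not (m_ex or m_in):
                raise GeneModelError(f"unknown region label {reg.label!r}")
            kind = "exon" if m_ex else "intron" if m_in else "utr"
            if kind == "exon" and prev_kind == "exon":
                raise GeneModelError("adjacent exons must be separated by an intron")
            if kind == "intron" and prev_kind != "exon":
                raise GeneModelError("intron must follow an exon")
            prev_kind = kind
            pos = reg.end
        cds_len = sum(r.length for r in self.regions if _EXON_RE.match(r.label))
        if cds_len and (cds_len - self.coding_offset) % 3 != 0:
            raise GeneModelError(
                f"concatenated exon length {cds_len} minus offset "
                f"{self.coding_offset} is not divisible by 3"
            )

    # -- basic geometry ----------------------------------------------------

    @property
    def total_length(self) -> int:
        return self.regions[-1].end

    @property
    def exon_regions(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if _EXON_RE.match(r.label))

    @property
    def intron_regions(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if _INTRON_RE.match(r.label))

    def region_lengths(self) -> dict[str, int]:
        return {r.label: r.length for r in self.regions}

    def assign_region(self, position: int) -> str:
        """Label of the unique region containing ``position`` (0-based)."""
        if not 0 <= position < self.total_length:
            raise GeneModelError(
                f"position {position} outside [0, {self.total_length})"
            )
        lo, hi = 0, len(self.regions) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if position >= self.regions[mid].end:
                lo = mid + 1
            else:
                hi = mid
        return self.regions[lo].label

    def region(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise GeneModelError(f"no region labelled {label!r}")

    # -- coding coordinates ------------------------------------------------

    def cds_positions(self) -> list[int]:
        """Gene-coordinate positions of the in-frame CDS, 5'→3'."""
        cat = [p for r in self.exon_regions for p in range(r.start, r.end)]
        return cat[self.coding_offset:]

    def cds_index_of(self, position: int) -> int | None:
        """Index of ``position`` within the in-frame CDS, or None if noncoding."""
        idx = 0
        for r in self.exon_regions:
            if r.contains(position):
                idx += position - r.start
                idx -= self.coding_offset
                return idx if idx >= 0 else None
            idx += r.length
        return None

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(r.label, r.start, r.end) for r in self.regions],
            columns=["label", "start", "end"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, coding_offset: int = 0,
                 strand: str = "+", name: str = "gene") -> "GeneModel":
        df = pd.read_csv(path, sep="\t")
        regions = tuple(
            Region(str(row.label), int(row.start), int(row.end))
            for row in df.itertuples()
        )
        return cls(regions, coding_offset=coding_offset, strand=strand, name=name)

    def to_gff3(self, path: str | Path, seqid: str | None = None) -> None:
        """Write the model as GFF3 (1-based inclusive coordinates)."""
        seqid = seqid or self.name
        lines = ["##gff-version 3"]
        L = self.total_length
        lines.append(
            f"{seqid}\tcandgene\tgene\t1\t{L}\t.\t{self.strand}\t.\tID={self.name}"
        )
        phase_pos = 0
        for r in self.regions:
            if r.label == FIVE_UTR:
                ftype = "five_prime_UTR"
            elif r.label == THREE_UTR:
                ftype = "three_prime_UTR"
            elif _EXON_RE.match(r.label):
                ftype = "exon"
            else:
                continue  # introns are implied by gaps between exons
            lines.append(
                f"{seqid}\tcandgene\t{ftype}\t{r.start + 1}\t{r.end}\t.\t"
                f"{self.strand}\t.\tID={r.label};Parent={self.name}"
            )
            if ftype == "exon":
                phase = (3 - (phase_pos - self.coding_offset) % 3) % 3 \
                    if phase_pos >= self.coding_offset else 0
                lines.append(
                    f"{seqid}\tcandgene\tCDS\t{r.start + 1}\t{r.end}\t.\t"
                    f"{self.strand}\t{(phase_pos - self.coding_offset) % 3 if phase_pos else self.coding_offset}\t"
                    f"ID=cds_{r.label};Parent={self.name}"
                )
                phase_pos += r.length
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path, name: str = "gene") -> "GeneModel":
        """Read a single-gene model from GFF3; introns inferred from exon gaps."""
        feats: list[tuple[str, int, int, str]] = []
        strand = "+"
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneModelError(f"malformed GFF3 record at line {lineno}")
            _, _, ftype, start, end, _, strd, _, _ = parts
            if ftype in {"five_prime_UTR", "three_prime_UTR", "exon"}:
                feats.append((ftype, int(start) - 1, int(end), strd))
                strand = strd if strd in "+-" else strand
        feats.sort(key=lambda f: f[1])
        regions: list[Region] = []
        exon_no = intron_no = 0
        prev_exon_end: int | None = None
        for ftype, start, end, _ in feats:
            if ftype == "five_prime_UTR":
                regions.append(Region(FIVE_UTR, start, end))
            elif ftype == "three_prime_UTR":
                regions.append(Region(THREE_UTR, start, end))
            else:
                if prev_exon_end is not None and start > prev_exon_end:
                    intron_no += 1
                    regions.append(Region(f"intron_{intron_no}", prev_exon_end, start))
                exon_no += 1
                regions.append(Region(f"exon_{exon_no}", start, end))
                prev_exon_end = end
        regions.sort(key=lambda r: r.start)
        return cls(tuple(regions), strand=strand, name=name)


def gene_model_from_lengths(
    layout: Iterable[tuple[str, int]],
    coding_offset: int = 0,
    strand: str = "+",
    name: str = "gene",
) -> GeneModel:
    """Build a :class:`GeneModel` from ordered (label, length) pairs."""
    regions, pos = [], 0
    for label, length in layout:
        regions.append(Region(label, pos, pos + int(length)))
        pos += int(length)
    return GeneModel(tuple(regions), coding_offset=coding_offset,
                     strand=strand, name=name)


def assign_region(model: GeneModel, position: int) -> str:
    """Functional alias for :meth:`GeneModel.assign_region`."""
    return model.assign_region(position)
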