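"""Genome metadata, coordinate conventions and the experiment design table.

All coordinates in this package are 0-based, half-open (BED/BigWig
convention): a CTSS at basepair ``p`` occupies the interval ``[p, p + 1)``.
1-based coordinates from external annotation are converted at the I/O
boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

STRANDS = ("+", "-")
#: Strand code for unstranded features (enhancers, merged exports).
UNSTRANDED = "."

__all__ = [
    "GenomeInfo",
    "DesignMatrix",
    "GenomicInterval",
    "read_chrom_sizes",
    "load_design",
    "write_design",
    "STRANDS",
    "UNSTRANDED",
]


class GenomeInfo:
    """Chromosome names and lengths (a parsed ``chrom.sizes``).

    Parameters
    ----------
    lengths
        Mapping of chromosome name to length in basepairs.  Names must be
        unique (guaranteed by the dict) and lengths positive.
    """

    def __init__(self, lengths: dict[str, int]):
        if not lengths:
            raise ValueError("GenomeInfo requires at least one chromosome")
        for chrom, length in lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self.lengths: dict[str, int] = {str(c): int(n) for c, n in lengths.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self):
        return iter(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        total = sum(self.lengths.values())
        return f"GenomeInfo({len(self.lengths)} chromosomes, {total:,} bp)"

    def to_chrom_sizes(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path: str) -> GenomeInfo:
    """Read a two-column UCSC ``chrom.sizes`` file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            if chrom in lengths:
                raise ValueError(f"duplicate chromosome {chrom!r} in {path}")
            lengths[chrom] = int(size)
    return GenomeInfo(lengths)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self):
        if self.strand not in (*STRANDS, UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def validate(self, genome: GenomeInfo) -> "GenomicInterval":
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome[self.chrom]}"
            )
        return self

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap test, strand-insensitive."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DesignMatrix:
    """Sample sheet: one row per sample with class, optional batch and the
    paths to its plus- and minus-strand CTSS tracks.

    Row order is meaningful: it fixes the column order of every count
    matrix produced downstream.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample", "class", "bw_plus", "bw_minus")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        samples = self.table["sample"].astype(str)
        dup = samples[samples.duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate sample ids in design: {sorted(set(dup))}")
        if "batch" not in self.table.columns:
            # absent batch column == a single batch
            self.table = self.table.assign(batch="A")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].astype(str).tolist()

    @property
    def classes(self) -> list[str]:
        return self.table["class"].astype(str).tolist()

    def __len__(self) -> int:
        return len(self.table)

    def track_paths(self) -> list[tuple[str, str, str]]:
        """Yield (sample, plus path, minus path) in design order."""
        return list(
            zip(self.samples, self.table["bw_plus"], self.table["bw_minus"])
        )


def load_design(path: str, genome: GenomeInfo | None = None,
                check_files: bool = True) -> DesignMatrix:
    """Load and validate a tab-separated design table.

    The file must have a header with at least the columns
    ``sample``, ``class``, ``bw_plus``, ``bw_minus``; ``batch`` is optional.
    Relative track paths are resolved against the design file's directory.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    base = os.path.dirname(os.path.abspath(path))
    design = DesignMatrix(table)
    for col in ("bw_plus", "bw_minus"):
        design.table[col] = [
            p if os.path.isabs(p) else os.path.join(base, p)
            for p in design.table[col]
        ]
    if check_files:
        for sample, plus, minus in design.track_paths():
            for p in (plus, minus):
                if not os.path.exists(p):
                    raise FileNotFoundError(
                        f"track file for sample {sample!r} not found: {p}"
                    )
    return design


def write_design(design: DesignMatrix, path: str) -> None:
    design.table.to_csv(path, sep="\t", index=False)
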