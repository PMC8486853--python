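"""Core genomic containers shared across the pipeline.

Coordinates are 0-based, half-open (BED convention) throughout. Signal
tracks are fixed-bin per-chromosome vectors carrying a normalization
state so that downstream quantification can refuse raw (un-normalized)
input where 1x-coverage units are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

RAW = "raw"
RPGC = "RPGC"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chrom/start/end span; the unit of all peak/enhancer/anchor arithmetic."""

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def distance_to(self, other: "GenomicInterval") -> float:
        """Nearest-edge gap between two intervals; 0 if they overlap.

        Intervals on different chromosomes are infinitely far apart.
        """
        if self.chrom != other.chrom:
            return float("inf")
        if self.start < other.end and other.start < self.end:
            return 0.0
        return float(max(self.start, other.start) - min(self.end, other.end))

    def distance_to_point(self, chrom: str, pos: int) -> float:
        """Nearest-edge gap to a point; 0 if the point lies inside."""
        if self.chrom != chrom:
            return float("inf")
        if self.start <= pos < self.end:
            return 0.0
        return float(max(self.start - pos, pos - (self.end - 1)))


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: strand-aware TSS."""

    gene_id: str
    name: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass
class SignalTrack:
    """Fixed-bin coverage vectors per chromosome.

    data maps chromosome name -> vector of length ceil(chrom_len / bin_size).
    Values are mean per-base coverage within the bin.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    norm: str = RAW
    mark: str = ""
    stage: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.norm not in (RAW, RPGC):
            raise ValueError(f"unknown normalization state {self.norm!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    def chrom_length(self, chrom: str) -> int:
        # Bins are full-width by construction in this package (bin size
        # divides chromosome length); length is recovered from the vector.
        return len(self.data[chrom]) * self.bin_size

    def genome_mean(self) -> float:
        """Base-weighted genome-wide mean coverage."""
        total = sum(float(v.sum()) * self.bin_size for v in self.data.values())
        nbases = sum(len(v) * self.bin_size for v in self.data.values())
        return total / nbases

    def copy_with(self, **kwargs) -> "SignalTrack":
        new = replace(self, **kwargs)
        new.data = {c: v.copy() for c, v in new.data.items()}
        return new


def intervals_to_arrays(intervals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a list of GenomicInterval into (chrom, start, end) arrays."""
    chroms = np.array([iv.chrom for iv in intervals], dtype=object)
    starts = np.array([iv.start for iv in intervals], dtype=int)
    ends = np.array([iv.end for iv in intervals], dtype=int)
    return chroms, starts, ends
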