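"""Genomic coordinate primitives: regions, bin grids and region-string parsing.

All coordinates are 0-based half-open ``[start, end)``.  Printed genome-browser
style strings such as ``"chr6:134,835,000-135,835,000"`` are parsed under the
same convention; thousands separators and both hyphen and en-dash range
separators are accepted because published coordinates use either.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicRegion",
    "BinGrid",
    "RegionParseError",
    "parse_region",
    "format_region",
    "make_bin_grid",
    "tss_bin_of",
]


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``chrom:[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name; must be non-empty.
    start, end : int
        0-based start (inclusive) and end (exclusive); ``0 <= start < end``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicRegion") -> "GenomicRegion | None":
        if not self.overlaps(other):
            return None
        return GenomicRegion(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


# chrom : start - end, commas optional, hyphen or en-dash (U+2013)
_REGION_RE = re.compile(
    r"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>[\d,]+)\s*[-–]\s*(?P<end>[\d,]+)\s*$"
)


def parse_region(text: str) -> GenomicRegion:
    """Parse ``chrom:start-end`` into a :class:`GenomicRegion`.

    Commas as thousands separators and en-dash range separators are accepted,
    so coordinates can be pasted verbatim from figures or genome browsers.

    >>> parse_region("chr6:134,835,000-135,835,000")
    GenomicRegion(chrom='chr6', start=134835000, end=135835000)
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start >= end:
        raise RegionParseError(
            f"region start must precede end, got {start} >= {end} in {text!r}"
        )
    return GenomicRegion(m.group("chrom"), start, end)


def format_region(region: GenomicRegion) -> str:
    """Canonical ``chrom:start-end`` string (no separators); inverse of
    :func:`parse_region` on canonical strings."""
    return f"{region.chrom}:{region.start}-{region.end}"


@dataclass(frozen=True)
class BinGrid:
    """A tiling of a region into fixed-width bins.

    Bin ``i`` spans ``[start + i*resolution, min(start + (i+1)*resolution, end))``;
    the last bin may be narrower when the region length is not a multiple of
    the resolution.
    """

    region: GenomicRegion
    resolution: int
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        n = -(-len(self.region) // self.resolution)  # ceil division
        object.__setattr__(self, "n_bins", n)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.region.start + self.resolution * np.arange(self.n_bins)

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.resolution, self.region.end)

    def bin_region(self, i: int) -> GenomicRegion:
        if not 0 <= i < self.n_bins:
            raise IndexError(f"bin index {i} out of range [0, {self.n_bins})")
        return GenomicRegion(
            self.region.chrom, int(self.bin_starts[i]), int(self.bin_ends[i])
        )


def make_bin_grid(region: GenomicRegion, resolution: int) -> BinGrid:
    """Tile ``region`` into bins of ``resolution`` bp (last bin clipped)."""
    return BinGrid(region=region, resolution=resolution)


def tss_bin_of(grid: BinGrid, tss: int) -> int:
    """Index of the bin containing base position ``tss`` (half-open bins)."""
    if not grid.region.contains(tss):
        raise ValueError(
            f"TSS position {tss} outside grid region {format_region(grid.region)}"
        )
    return (tss - grid.region.start) // grid.resolution
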