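"""Per-base signal tracks (ATAC coverage, contribution scores) as step functions.

A :class:`SignalTrack` stores sorted, non-overlapping ``[start, end)`` intervals
with one value each over a window; bases not covered by any interval carry
value 0, matching coverage-track semantics.  Windows in this pipeline are at
most a few Mb, so dense per-base views are cheap and used for quantiles and
bin statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import BinGrid, GenomicRegion

__all__ = ["SignalTrack", "read_bedgraph", "write_bedgraph", "bin_signal"]


@dataclass(frozen=True)
class SignalTrack:
    region: GenomicRegion
    starts: np.ndarray  # interval starts, ascending
    ends: np.ndarray    # interval ends
    values: np.ndarray  # one value per interval

    def __post_init__(self) -> None:
        s, e, v = (np.asarray(a) for a in (self.starts, self.ends, self.values))
        object.__setattr__(self, "starts", s.astype(np.int64))
        object.__setattr__(self, "ends", e.astype(np.int64))
        object.__setattr__(self, "values", v.astype(np.float64))
        if not (len(s) == len(e) == len(v)):
            raise ValueError("starts, ends, values must have equal length")
        if len(s):
            if np.any(e <= s):
                raise ValueError("every interval needs end > start")
            if np.any(s[1:] < e[:-1]):
                raise ValueError("intervals must be sorted and non-overlapping")
            if s[0] < self.region.start or e[-1] > self.region.end:
                raise ValueError("intervals must lie within the track region")

    @classmethod
    def empty(cls, region: GenomicRegion) -> "SignalTrack":
        z = np.empty(0, dtype=np.int64)
        return cls(region, z, z.copy(), np.empty(0))

    @classmethod
    def from_dense(cls, region: GenomicRegion, values: np.ndarray) -> "SignalTrack":
        """Build a run-length encoded track from one value per base."""
        values = np.asarray(values, dtype=np.float64)
        if len(values) != len(region):
            raise ValueError("dense array length must equal region length")
        if len(values) == 0:
            return cls.empty(region)
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change)) + region.start
        ends = np.concatenate((change, [len(values)])) + region.start
        vals = values[starts - region.start]
        keep = vals != 0.0
        return cls(region, starts[keep], ends[keep], vals[keep])

    def to_dense(self) -> np.ndarray:
        """One value per base over the track region (uncovered bases are 0)."""
        out = np.zeros(len(self.region), dtype=np.float64)
        off = self.region.start
        for s, e, v in zip(self.starts, self.ends, self.values):
            out[s - off : e - off] = v
        return out

    def integral(self) -> float:
        """Sum of value x length over all intervals."""
        return float(np.dot(self.ends - self.starts, self.values))

    def clip(self, region: GenomicRegion) -> "SignalTrack":
        if region.chrom != self.region.chrom:
            raise ValueError("cannot clip a track to a different chromosome")
        s = np.maximum(self.starts, region.start)
        e = np.minimum(self.ends, region.end)
        keep = s < e
        return SignalTrack(region, s[keep], e[keep], self.values[keep])


def read_bedgraph(path, region: GenomicRegion) -> SignalTrack:
    """Read a 4-column bedGraph restricted to ``region``.

    Input intervals are 0-based half-open and clipped to the region; intervals
    on other chromosomes are ignored.  Overlapping input intervals within the
    region are an error because a step function admits only one value per base.
    """
    starts, ends, values = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if e <= s:
                raise ValueError(f"{path}:{ln}: interval end {e} <= start {s}")
            try:
                val = float(v)
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-numeric value {v!r}") from err
            if chrom != region.chrom:
                continue
            s, e = max(s, region.start), min(e, region.end)
            if s >= e:
                continue
            starts.append(s)
            ends.append(e)
            values.append(val)
    if not starts:
        return SignalTrack.empty(region)
    order = np.lexsort((ends, starts))
    s = np.asarray(starts)[order]
    e = np.asarray(ends)[order]
    v = np.asarray(values)[order]
    if np.any(s[1:] < e[:-1]):
        i = int(np.flatnonzero(s[1:] < e[:-1])[0])
        raise ValueError(
            f"{path}: overlapping bedGraph intervals "
            f"[{s[i]},{e[i]}) and [{s[i+1]},{e[i+1]})"
        )
    return SignalTrack(region, s, e, v)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.region.chrom}\t{s}\t{e}\t{v:g}\n")


def bin_signal(track: SignalTrack, grid: BinGrid, stat: str = "mean") -> np.ndarray:
    """Aggregate a per-base track into one value per grid bin.

    ``mean`` divides by the full bin width (uncovered bases count as 0),
    ``sum`` conserves the track integral across bins, ``max`` takes the
    per-base maximum (0 for bins with any uncovered base and no positive
    signal above it).
    """
    if stat not in ("mean", "sum", "max"):
        raise ValueError(f"stat must be mean|sum|max, got {stat!r}")
    if not (
        track.region.chrom == grid.region.chrom
        and track.region.start <= grid.region.start
        and track.region.end >= grid.region.end
    ):
        raise ValueError("track region must cover the grid region")
    dense = track.clip(grid.region).to_dense()
    out = np.empty(grid.n_bins, dtype=np.float64)
    off = grid.region.start
    for i, (s, e) in enumerate(zip(grid.bin_starts, grid.bin_ends)):
        chunk = dense[s - off : e - off]
        if stat == "mean":
            out[i] = chunk.sum() / (e - s)
        elif stat == "sum":
            out[i] = chunk.sum()
        else:
            out[i] = chunk.max() if len(chunk) else 0.0
    return out
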