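"""Spatial TSS neighborhoods, contribution-score retention, and the
differential TF-occupancy report.

The neighborhood of a gene is the set of bins whose layout position lies
within ``neighborhood_factor`` (default 3.0) mean interbin distances of the
TSS-containing bin — spatial, not genomic, proximity.  Within the analysis
window, bases carrying the top ``1 - contribution_quantile`` share of
contribution scores (default top 10%) that fall inside neighborhood bins are
retained and screened for TF motifs; per-family unique-site counts in two
conditions yield the differential occupancy report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import SpatialLayout
from .motifs import MotifHit, collapse_hits_by_family
from .regions import BinGrid, GenomicRegion
from .tracks import SignalTrack

__all__ = [
    "NeighborhoodSelection",
    "tss_neighborhood",
    "high_contribution_intervals",
    "OccupancyReport",
    "differential_occupancy",
    "write_report_tsv",
    "write_arcs_tsv",
]


@dataclass
class NeighborhoodSelection:
    """Bins spatially proximal to a TSS bin in the layout."""

    tss_bin: int
    radius: float
    member_bins: np.ndarray  # ascending bin indices, includes tss_bin
    member_regions: list[GenomicRegion]  # genomically merged member intervals

    def __post_init__(self) -> None:
        if self.tss_bin not in self.member_bins:
            raise ValueError("tss_bin must be a member of its own neighborhood")


def tss_neighborhood(
    layout: SpatialLayout, tss_bin: int, neighborhood_factor: float = 3.0
) -> NeighborhoodSelection:
    """All unmasked bins within ``factor x mean_interbin`` of the TSS bin
    (inclusive radius)."""
    nodes = layout.nodes
    if tss_bin not in nodes:
        raise ValueError(f"TSS bin {tss_bin} is masked or out of range")
    radius = neighborhood_factor * layout.mean_interbin
    dists = np.linalg.norm(layout.xy[nodes] - layout.xy[tss_bin], axis=1)
    members = nodes[dists <= radius]
    grid = layout.grid
    regions: list[GenomicRegion] = []
    for b in members:
        r = grid.bin_region(int(b))
        if regions and regions[-1].end == r.start:
            regions[-1] = GenomicRegion(r.chrom, regions[-1].start, r.end)
        else:
            regions.append(r)
    return NeighborhoodSelection(
        tss_bin=int(tss_bin),
        radius=float(radius),
        member_bins=members,
        member_regions=regions,
    )


def high_contribution_intervals(
    contrib: SignalTrack,
    window: GenomicRegion,
    quantile: float = 0.90,
    selection: NeighborhoodSelection | None = None,
) -> list[GenomicRegion]:
    """Bases in the top ``1 - quantile`` share of contribution scores that fall
    inside neighborhood bins, merged into maximal intervals.

    The threshold is the ``quantile`` of per-base scores across the whole
    window.  Retention requires a strictly positive score in addition to
    ``score >= threshold``: on sparse tracks the window quantile can be 0 and
    zero-contribution bases are never "high-contribution".
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if not (
        contrib.region.chrom == window.chrom
        and contrib.region.start <= window.start
        and contrib.region.end >= window.end
    ):
        raise ValueError("contribution track must cover the window")
    dense = contrib.clip(window).to_dense()
    if not np.any(dense):
        warnings.warn(
            "contribution track is all-zero over the window; nothing retained",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    threshold = float(np.quantile(dense, quantile))
    keep = (dense >= threshold) & (dense > 0)
    if selection is not None:
        member_mask = np.zeros(len(dense), dtype=bool)
        for r in selection.member_regions:
            s = max(r.start, window.start) - window.start
            e = min(r.end, window.end) - window.start
            if s < e:
                member_mask[s:e] = True
        keep &= member_mask
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    out = []
    for run in np.split(idx, breaks):
        out.append(
            GenomicRegion(window.chrom, window.start + int(run[0]),
                          window.start + int(run[-1]) + 1)
        )
    return out


@dataclass
class FamilyRow:
    family: str
    count_a: int
    count_b: int
    delta: int  # count_a - count_b
    # unified sites across conditions: (region, present in A, present in B)
    sites: list[tuple[GenomicRegion, bool, bool]] = field(default_factory=list)


@dataclass
class OccupancyReport:
    """Per-TF-family unique-site counts in two conditions, sorted by |delta|."""

    condition_a: str
    condition_b: str
    rows: list[FamilyRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tf_family": r.family,
                    f"count_{self.condition_a}": r.count_a,
                    f"count_{self.condition_b}": r.count_b,
                    "delta": r.delta,
                }
                for r in self.rows
            ]
        )


def _merge_sites(
    sites_a: list[GenomicRegion], sites_b: list[GenomicRegion]
) -> list[tuple[GenomicRegion, bool, bool]]:
    tagged = [(r, True, False) for r in sites_a] + [(r, False, True) for r in sites_b]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    out: list[tuple[GenomicRegion, bool, bool]] = []
    for r, in_a, in_b in tagged:
        if out and r.chrom == out[-1][0].chrom and r.start < out[-1][0].end:
            prev, pa, pb = out[-1]
            out[-1] = (
                GenomicRegion(prev.chrom, prev.start, max(prev.end, r.end)),
                pa or in_a,
                pb or in_b,
            )
        else:
            out.append((r, in_a, in_b))
    return out


def differential_occupancy(
    hits_a: list[MotifHit],
    hits_b: list[MotifHit],
    condition_a: str = "A",
    condition_b: str = "B",
    family_map: dict[str, str] | None = None,
) -> OccupancyReport:
    """Compare per-family unique-site counts between two conditions.

    Sites overlapping across conditions are aligned so condition-specific
    footprints ("open in A, closed in B") are directly listable.  Counts are
    per-condition collapsed site counts; rows sort by descending |delta|,
    then family name.
    """
    sites_a = collapse_hits_by_family(hits_a, family_map)
    sites_b = collapse_hits_by_family(hits_b, family_map)
    rows = []
    for fam in sorted(set(sites_a) | set(sites_b)):
        sa = sites_a.get(fam, [])
        sb = sites_b.get(fam, [])
        rows.append(
            FamilyRow(
                family=fam,
                count_a=len(sa),
                count_b=len(sb),
                delta=len(sa) - len(sb),
                sites=_merge_sites(sa, sb),
            )
        )
    rows.sort(key=lambda r: (-abs(r.delta), r.family))
    return OccupancyReport(condition_a, condition_b, rows)


def write_report_tsv(report: OccupancyReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"tf_family\tcount_{report.condition_a}\tcount_{report.condition_b}"
            "\tdelta\tsites\n"
        )
        for r in report.rows:
            sites = ",".join(
                f"{s.chrom}:{s.start}-{s.end}"
                f"[{'A' if a else ''}{'B' if b else ''}]"
                for s, a, b in r.sites
            )
            fh.write(f"{r.family}\t{r.count_a}\t{r.count_b}\t{r.delta}\t{sites}\n")


def write_arcs_tsv(
    selection: NeighborhoodSelection, grid: BinGrid, path
) -> None:
    """Arcs between the TSS bin and each spatially proximal member bin."""
    starts = grid.bin_starts
    with open(path, "w") as fh:
        fh.write("tss_bin\ttss_start\tmember_bin\tmember_start\n")
        for b in selection.member_bins:
            if b == selection.tss_bin:
                continue
            fh.write(
                f"{selection.tss_bin}\t{starts[selection.tss_bin]}\t"
                f"{int(b)}\t{starts[int(b)]}\n"
            )
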