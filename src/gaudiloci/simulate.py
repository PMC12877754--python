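"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the data the spatial analysis
consumes: TAD-structured intrachromosomal Hi-C with power-law distance decay
(optionally Poisson-sampled), a genome with planted TF consensus sites,
condition-specific accessibility peaks over the bins holding those sites,
and contribution tracks concentrated in footprint-shaped bumps at the sites.
``simulate_condition_pair`` mirrors a vehicle-vs-treatment design: AP1 sites
accessible only in condition A near one locus, TCF/LEF sites accessible only
in condition B near another, over one shared genome and shared TADs.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic import ContactMatrix
from .regions import BinGrid, GenomicRegion, make_bin_grid, tss_bin_of
from .tracks import SignalTrack

__all__ = [
    "PlantedSite",
    "SimulationTruth",
    "PairConfig",
    "ConditionBundle",
    "simulate_hic",
    "simulate_genome",
    "simulate_tracks",
    "simulate_condition_pair",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlantedSite:
    family: str
    chrom: str
    start: int  # 0-based; site occupies [start, start + len(consensus))
    strand: str
    consensus: str
    condition: str  # condition in which the site is accessible


@dataclass
class SimulationTruth:
    tad_boundaries: list[int]
    planted_sites: list[PlantedSite] = field(default_factory=list)
    peak_bins: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0


def _tad_ids(n_bins: int, boundaries: list[int]) -> np.ndarray:
    b = np.asarray(sorted(boundaries), dtype=int)
    if len(b) and (b[0] <= 0 or b[-1] >= n_bins):
        raise ValueError("TAD boundaries must lie strictly inside the grid")
    return np.searchsorted(b, np.arange(n_bins), side="right")


def simulate_hic(
    grid: BinGrid,
    tad_boundaries: list[int],
    decay_alpha: float = 1.0,
    tad_boost: float = 3.0,
    depth: float = 100.0,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[ContactMatrix, SimulationTruth]:
    """Contact matrix with power-law distance decay and within-TAD boost.

    The expected count is ``depth * (1 + |i-j|)^(-alpha)``, multiplied by
    ``tad_boost`` when both bins share a TAD; the diagonal is ``depth``.
    ``noise='poisson'`` samples each upper-triangle entry once and mirrors it,
    so the matrix stays exactly symmetric.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if decay_alpha < 0 or tad_boost < 1:
        raise ValueError("need decay_alpha >= 0 and tad_boost >= 1")
    if noise not in ("poisson", "none"):
        raise ValueError(f"noise must be poisson|none, got {noise!r}")
    n = grid.n_bins
    tid = _tad_ids(n, tad_boundaries)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    sep = np.abs(i - j)
    mu = depth * (1.0 + sep) ** (-decay_alpha)
    mu *= np.where(tid[i] == tid[j], tad_boost, 1.0)
    np.fill_diagonal(mu, depth)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n)
        vals = np.zeros((n, n))
        vals[iu] = rng.poisson(mu[iu]).astype(float)
        vals = vals + np.triu(vals, k=1).T
    else:
        vals = (mu + mu.T) / 2.0
    truth = SimulationTruth(tad_boundaries=sorted(tad_boundaries), seed=seed)
    return ContactMatrix(grid, vals), truth


def simulate_genome(
    window: GenomicRegion,
    gc: float = 0.42,
    planted: list[tuple[str, int, str]] | None = None,
    seed: int = 0,
) -> tuple[str, list[tuple[str, int, str]]]:
    """I.i.d. background sequence with planted consensus strings.

    ``planted`` holds ``(consensus, genomic start, strand)``; minus-strand
    plants are written reverse-complemented so a forward scan of the plus
    strand recovers them as minus-strand hits.  Returns the window sequence
    (index 0 = ``window.start``) and the planted list.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    planted = list(planted or [])
    spans = []
    for cons, pos, strand in planted:
        if strand not in "+-":
            raise ValueError(f"invalid strand {strand!r}")
        if pos < window.start or pos + len(cons) > window.end:
            raise ValueError(f"planted site at {pos} outside window")
        spans.append((pos, pos + len(cons)))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"planted sites overlap at [{s2}, {e1})")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=len(window), p=probs)
    seq = bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes())
    for cons, pos, strand in planted:
        written = cons.upper() if strand == "+" else revcomp(cons.upper())
        seq[pos - window.start : pos - window.start + len(cons)] = written.encode()
    return seq.decode("ascii"), planted


def simulate_tracks(
    grid: BinGrid,
    peak_bins: list[int],
    peak_height: float = 5.0,
    basal: float = 0.5,
    noise_sd: float = 0.0,
    planted_sites: list[PlantedSite] | None = None,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack]:
    """Accessibility coverage and contribution-score tracks.

    ATAC coverage is ``basal`` everywhere plus ``peak_height`` over peak bins
    plus truncated Gaussian noise.  The contribution track is zero except for
    a triangular bump of height 1 spanning each planted site +/- 5 bp, the
    footprint-like shape that lets a top-quantile filter recover site cores
    before flanks.
    """
    if not peak_height > basal >= 0:
        raise ValueError("need peak_height > basal >= 0")
    n = len(grid.region)
    for b in peak_bins:
        if not 0 <= b < grid.n_bins:
            raise ValueError(f"peak bin {b} outside grid")
    atac = np.full(n, basal)
    off = grid.region.start
    for b in peak_bins:
        atac[grid.bin_starts[b] - off : grid.bin_ends[b] - off] += peak_height
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        atac = np.maximum(atac + rng.normal(0.0, noise_sd, size=n), 0.0)
    contrib = np.zeros(n)
    for site in planted_sites or []:
        s = site.start - 5
        e = site.start + len(site.consensus) + 5
        s_c, e_c = max(s, grid.region.start), min(e, grid.region.end)
        center = (s + e - 1) / 2.0
        half = (e - s) / 2.0
        pos = np.arange(s_c, e_c)
        bump = 1.0 - np.abs(pos - center) / half
        sl = slice(s_c - off, e_c - off)
        contrib[sl] = np.maximum(contrib[sl], bump)
    return (
        SignalTrack.from_dense(grid.region, atac),
        SignalTrack.from_dense(grid.region, contrib),
    )


@dataclass
class PairConfig:
    """Study-design parameters for the two-condition simulation.

    Defaults mirror the analysis scale: a 1 Mb window at 5 kb resolution
    (200 bins), five TADs, six AP1 sites accessible only in condition A near
    locus E and five TCF/LEF sites accessible only in condition B near locus
    L, sequencing depth 100 expected diagonal counts.
    """

    window: GenomicRegion = field(
        default_factory=lambda: GenomicRegion("chrS", 0, 1_000_000)
    )
    resolution: int = 5000
    tss_e: int = 302_500      # locus E TSS (bin 60)
    tss_l: int = 702_500      # locus L TSS (bin 140)
    tad_boundaries: list[int] = field(default_factory=lambda: [40, 80, 120, 160])
    n_ap1: int = 6
    n_tcf: int = 5
    ap1_consensus: str = "TGACTCA"
    tcf_consensus: str = "CTTTGTT"
    decay_alpha: float = 1.0
    tad_boost: float = 3.0
    depth: float = 100.0
    hic_noise: str = "none"   # "none" or "poisson"
    peak_height: float = 5.0
    basal: float = 0.5
    track_noise_sd: float = 0.0
    gc: float = 0.42


@dataclass
class ConditionBundle:
    name: str
    hic: ContactMatrix
    atac: SignalTrack
    contrib: SignalTrack
    genome: str  # shared window sequence


def _site_positions(
    cfg: PairConfig, grid: BinGrid, tss: int, n_sites: int, motif_len: int
) -> list[int]:
    """Deterministic site positions in the bins flanking a TSS bin.

    Sites cycle through the TSS bin and its +/- 1, +/- 2 genomic neighbors
    (spatially proximal through the backbone and shared TAD) at distinct
    in-bin offsets so plants never overlap.
    """
    tss_bin = tss_bin_of(grid, tss)
    bins = [tss_bin, tss_bin - 1, tss_bin + 1, tss_bin - 2, tss_bin + 2]
    bins = [b for b in bins if 0 <= b < grid.n_bins]
    positions = []
    for k in range(n_sites):
        b = bins[k % len(bins)]
        offset = 500 + 600 * (k // len(bins)) + 137 * k
        positions.append(int(grid.bin_starts[b]) + offset)
    return positions


def simulate_condition_pair(
    cfg: PairConfig | None = None, seed: int = 0
) -> tuple[ConditionBundle, ConditionBundle, SimulationTruth]:
    """Vehicle-vs-treatment style bundle pair over one shared genome.

    AP1 consensus sites near locus E carry accessibility peaks and
    contribution bumps only in condition A; TCF/LEF sites near locus L only
    in condition B.  Hi-C is drawn per condition with the same TAD structure
    (identical matrices when ``hic_noise='none'``).
    """
    cfg = cfg or PairConfig()
    grid = make_bin_grid(cfg.window, cfg.resolution)
    for tss in (cfg.tss_e, cfg.tss_l):
        if not cfg.window.contains(tss):
            raise ValueError(f"locus TSS {tss} outside window")
    ss = np.random.SeedSequence(seed)
    s_genome, s_hic_a, s_hic_b, s_trk_a, s_trk_b = [
        int(s) % (2**31) for s in ss.generate_state(5)
    ]
    if cfg.hic_noise == "none":
        s_hic_b = s_hic_a  # identical draws; noiseless matrices are equal anyway

    chrom = cfg.window.chrom
    ap1_pos = _site_positions(cfg, grid, cfg.tss_e, cfg.n_ap1, len(cfg.ap1_consensus))
    tcf_pos = _site_positions(cfg, grid, cfg.tss_l, cfg.n_tcf, len(cfg.tcf_consensus))
    sites = [
        PlantedSite("AP1", chrom, p, "+" if k % 2 == 0 else "-",
                    cfg.ap1_consensus, "A")
        for k, p in enumerate(ap1_pos)
    ] + [
        PlantedSite("TCF/LEF", chrom, p, "+" if k % 2 == 0 else "-",
                    cfg.tcf_consensus, "B")
        for k, p in enumerate(tcf_pos)
    ]
    genome, _ = simulate_genome(
        cfg.window,
        gc=cfg.gc,
        planted=[(s.consensus, s.start, s.strand) for s in sites],
        seed=s_genome,
    )
    peak_bins = {
        "A": sorted({tss_bin_of(grid, s.start) for s in sites if s.condition == "A"}),
        "B": sorted({tss_bin_of(grid, s.start) for s in sites if s.condition == "B"}),
    }
    bundles = {}
    for cond, s_hic, s_trk in (("A", s_hic_a, s_trk_a), ("B", s_hic_b, s_trk_b)):
        cm, _ = simulate_hic(
            grid,
            cfg.tad_boundaries,
            decay_alpha=cfg.decay_alpha,
            tad_boost=cfg.tad_boost,
            depth=cfg.depth,
            noise=cfg.hic_noise,
            seed=s_hic,
        )
        cond_sites = [s for s in sites if s.condition == cond]
        atac, contrib = simulate_tracks(
            grid,
            peak_bins[cond],
            peak_height=cfg.peak_height,
            basal=cfg.basal,
            noise_sd=cfg.track_noise_sd,
            planted_sites=cond_sites,
            seed=s_trk,
        )
        bundles[cond] = ConditionBundle(cond, cm, atac, contrib, genome)
    truth = SimulationTruth(
        tad_boundaries=sorted(cfg.tad_boundaries),
        planted_sites=sites,
        peak_bins=peak_bins,
        seed=seed,
    )
    return bundles["A"], bundles["B"], truth
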