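"""End-to-end orchestration: balance -> layout -> occupancy geometry ->
per-bin signal -> TSS neighborhood -> contribution filter -> motif scan ->
differential report, with a run manifest for reproducibility audits."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (
    NeighborhoodSelection,
    OccupancyReport,
    differential_occupancy,
    high_contribution_intervals,
    tss_neighborhood,
    write_arcs_tsv,
    write_report_tsv,
)
from .config import PipelineConfig
from .geometry import GaudiPlot, gaudi_geojson, render_gaudi, voronoi_occupancy
from .hic import ContactMatrix, InteractionGraph, ice_balance
from .io import write_bed
from .layout import SpatialLayout, compute_layout, write_layout_tsv
from .motifs import MotifHit, scan_pwms, write_hits_bed
from .pwm import PWM
from .regions import BinGrid, GenomicRegion, tss_bin_of
from .tracks import SignalTrack, bin_signal

logger = logging.getLogger(__name__)

__all__ = ["ConditionResult", "analyze_condition", "compare_conditions", "run_all"]


@dataclass
class ConditionResult:
    """Everything one condition's pass through the pipeline produces."""

    name: str
    balanced: ContactMatrix
    graph: InteractionGraph
    layout: SpatialLayout
    gaudi: GaudiPlot | None
    atac_per_bin: np.ndarray
    selection: NeighborhoodSelection
    retained: list[GenomicRegion]
    hits: list[MotifHit]


def analyze_condition(
    contacts: ContactMatrix,
    atac: SignalTrack,
    contrib: SignalTrack,
    genome: str,
    tss: int,
    pwms: list[PWM],
    config: PipelineConfig | None = None,
    name: str = "condition",
    make_gaudi: bool = True,
) -> ConditionResult:
    """Run the full single-condition analysis over one genomic window.

    ``genome`` is the window's plus-strand sequence (index 0 at the window
    start).  Motifs are scanned only inside the retained high-contribution
    intervals that fall in bins spatially near the TSS.
    """
    cfg = config or PipelineConfig()
    grid = contacts.grid
    if len(genome) != len(grid.region):
        raise ValueError("genome sequence must cover the analysis window")
    balanced = ice_balance(contacts)
    layout, graph = compute_layout(balanced, cfg.top_fraction, seed=cfg.seed)
    gaudi = None
    if make_gaudi:
        gaudi = voronoi_occupancy(
            layout,
            buffer_factor=cfg.buffer_factor,
            dummy_count=cfg.dummy_count,
            dummy_radius_factor=cfg.dummy_radius_factor,
            disc_segments=cfg.disc_segments,
        )
    atac_per_bin = bin_signal(atac, grid, stat="mean")
    selection = tss_neighborhood(
        layout, tss_bin_of(grid, tss), cfg.neighborhood_factor
    )
    retained = high_contribution_intervals(
        contrib, grid.region, cfg.contribution_quantile, selection
    )
    hits: list[MotifHit] = []
    for r in retained:
        seq = genome[r.start - grid.region.start : r.end - grid.region.start]
        hits.extend(
            scan_pwms(
                seq, r.start, pwms, cfg.pwm_score_fraction, chrom=grid.region.chrom
            )
        )
    return ConditionResult(
        name, balanced, graph, layout, gaudi, atac_per_bin, selection, retained, hits
    )


def compare_conditions(
    result_a: ConditionResult,
    result_b: ConditionResult,
    family_map: dict[str, str] | None = None,
) -> OccupancyReport:
    ga, gb = result_a.layout.grid, result_b.layout.grid
    if ga != gb:
        raise ValueError("conditions were analyzed over different grids")
    return differential_occupancy(
        result_a.hits, result_b.hits, result_a.name, result_b.name, family_map
    )


# --------------------------------------------------------------------------
# file-driven runs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    version: str = __version__
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def read_config_file(path) -> dict:
    """Plain ``key = value`` config text (``#`` comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            k, v = (t.strip() for t in line.split("=", 1))
            out[k] = v
    return out


def _write_condition_artifacts(
    res: ConditionResult, outdir: Path, cfg: PipelineConfig
) -> list[str]:
    grid = res.layout.grid
    paths = []

    def emit(name: str, writer) -> None:
        p = outdir / name
        writer(p)
        paths.append(str(p))

    emit(f"layout_{res.name}.tsv", lambda p: write_layout_tsv(res.layout, p))
    if res.gaudi is not None:
        values = res.atac_per_bin[[poly.bin_index for poly in res.gaudi.polygons]]
        emit(
            f"gaudi_{res.name}.svg",
            lambda p: render_gaudi(
                res.gaudi,
                values,
                highlight={res.selection.tss_bin},
                out=p,
                tss_bin=res.selection.tss_bin,
                neighborhood_radius=res.selection.radius,
            ),
        )
        emit(
            f"gaudi_{res.name}.geojson",
            lambda p: gaudi_geojson(res.gaudi, values, out=p),
        )
    emit(
        f"bins_{res.name}.tsv",
        lambda p: np.savetxt(
            p,
            np.column_stack([grid.bin_starts, res.atac_per_bin]),
            fmt=("%d", "%.10g"),
            delimiter="\t",
            header="bin_start\tatac_mean",
            comments="",
        ),
    )
    emit(f"arcs_{res.name}.tsv", lambda p: write_arcs_tsv(res.selection, grid, p))
    emit(f"retained_{res.name}.bed", lambda p: write_bed(res.retained, p))
    emit(f"hits_{res.name}.bed", lambda p: write_hits_bed(res.hits, p))
    return paths


def run_all(config_path, outdir) -> Path:
    """Execute the pipeline from a key=value config file; returns the
    artifact directory.  See the CLI reference in the README for the keys."""
    from .io import read_fasta
    from .hic import read_contacts
    from .pwm import read_pwms
    from .regions import make_bin_grid, parse_region
    from .tracks import read_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = read_config_file(config_path)
    pipe_keys = set(PipelineConfig.__dataclass_fields__)
    cfg = PipelineConfig.from_dict(
        {k: v for k, v in raw.items() if k in pipe_keys}
    )
    manifest = RunManifest(config=dict(raw), seed=cfg.seed)
    region = parse_region(raw["window"])
    grid = make_bin_grid(region, cfg.resolution)
    tss = int(raw["tss"].replace(",", ""))
    conditions = [c.strip() for c in raw.get("conditions", "A").split(",")]

    stage = "load"
    try:
        t0 = time.perf_counter()
        pwms = read_pwms(raw["motifs"], raw.get("motif_format", "meme"))
        genome = read_fasta(raw["genome"])[region.chrom]
        if len(genome) > len(region):  # whole-chromosome FASTA: cut the window
            genome = genome[region.start : region.end]
        manifest.timings["load"] = time.perf_counter() - t0
        for key in ("motifs", "genome"):
            manifest.inputs[raw[key]] = _sha256(Path(raw[key]))

        results = []
        for cond in conditions:
            stage = f"analyze_{cond}"
            t0 = time.perf_counter()
            contacts_p = raw[f"contacts_{cond}"]
            atac_p = raw[f"atac_{cond}"]
            contrib_p = raw[f"contrib_{cond}"]
            for p in (contacts_p, atac_p, contrib_p):
                manifest.inputs[p] = _sha256(Path(p))
            res = analyze_condition(
                read_contacts(contacts_p, grid),
                read_bedgraph(atac_p, region),
                read_bedgraph(contrib_p, region),
                genome,
                tss,
                pwms,
                cfg,
                name=cond,
            )
            manifest.outputs += _write_condition_artifacts(res, outdir, cfg)
            manifest.timings[stage] = time.perf_counter() - t0
            results.append(res)

        if len(results) == 2:
            stage = "report"
            t0 = time.perf_counter()
            report = compare_conditions(results[0], results[1])
            rp = outdir / "report.tsv"
            write_report_tsv(report, rp)
            manifest.outputs.append(str(rp))
            manifest.timings["report"] = time.perf_counter() - t0
    except Exception:
        manifest.failed_stage = stage
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    logger.info("run complete: %d artifacts in %s", len(manifest.outputs), outdir)
    return outdir
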