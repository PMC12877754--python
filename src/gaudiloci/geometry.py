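"""Gaudi-plot geometry: Voronoi cells closed by dummy nodes, clipped by
per-bin buffer discs, and SVG / GeoJSON rendering.

Each unmasked bin's spatial occupancy is the intersection of its Voronoi cell
(computed over the bin points plus a distant ring of dummy points that keeps
every cell finite) with a buffer disc of radius ``buffer_factor`` times the
mean interbin distance, centred on the bin.  Discs are approximated by
regular polygons so every operation is exact polygon-polygon intersection;
a 64-gon under-covers a true disc by < 0.17% in area.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

from .layout import SpatialLayout

logger = logging.getLogger(__name__)

# coordinate resolution of occupancy polygons (layout units)
_COORD_GRID = 1e-9

__all__ = [
    "OccupancyPolygon",
    "GaudiPlot",
    "voronoi_occupancy",
    "render_gaudi",
    "gaudi_geojson",
]


@dataclass
class OccupancyPolygon:
    bin_index: int
    vertices: np.ndarray  # closed CCW ring, shape (k, 2), first == last
    area: float

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class GaudiPlot:
    layout: SpatialLayout
    polygons: list[OccupancyPolygon]  # one per unmasked bin, in node order
    signal: np.ndarray | None = None  # per-polygon values


def _regular_polygon(center: np.ndarray, radius: float, segments: int) -> Polygon:
    theta = 2.0 * np.pi * np.arange(segments) / segments
    ring = center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return Polygon(ring)


def _dejitter(pts: np.ndarray, eps: float) -> np.ndarray:
    """Separate coincident points deterministically (needed for Voronoi)."""
    out = pts.copy()
    moved = 0
    for k in range(len(out)):
        while np.any(
            np.linalg.norm(out[:k] - out[k], axis=1) < 1e-9
        ):
            angle = 2.0 * np.pi * (k + moved) / max(len(out), 1)
            out[k] = out[k] + eps * np.array([np.cos(angle), np.sin(angle)])
            moved += 1
    if moved:
        logger.info("voronoi_occupancy: jittered %d coincident points", moved)
    return out


def _halfplane_cell(
    pts: np.ndarray, i: int, bound: float
) -> Polygon:
    """Voronoi cell of point i as an intersection of bisector half-planes."""
    cell = box(
        pts[i, 0] - bound, pts[i, 1] - bound, pts[i, 0] + bound, pts[i, 1] + bound
    )
    p = pts[i]
    for j in range(len(pts)):
        if j == i:
            continue
        q = pts[j]
        mid = (p + q) / 2.0
        normal = q - p
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            continue
        normal = normal / nn
        tang = np.array([-normal[1], normal[0]])
        a = mid + tang * 4 * bound
        b = mid - tang * 4 * bound
        half = Polygon(
            [a, b, b - normal * 8 * bound, a - normal * 8 * bound]
        )
        cell = cell.intersection(half)
        if cell.is_empty:
            break
    return cell


def voronoi_occupancy(
    layout: SpatialLayout,
    buffer_factor: float = 1.5,
    dummy_count: int = 36,
    dummy_radius_factor: float = 4.0,
    disc_segments: int = 64,
) -> GaudiPlot:
    """Compute per-bin occupancy polygons (Voronoi cell ∩ buffer disc)."""
    if buffer_factor <= 0:
        raise ValueError("buffer_factor must be positive")
    nodes = layout.nodes
    if len(nodes) == 0:
        raise ValueError("layout has no unmasked bins")
    pts = layout.xy[nodes]
    mib = layout.mean_interbin if np.isfinite(layout.mean_interbin) else 1.0
    pts = _dejitter(pts, eps=1e-6 * max(mib, 1e-6))
    r = buffer_factor * mib

    centroid = pts.mean(axis=0)
    spread = float(np.linalg.norm(pts - centroid, axis=1).max()) if len(pts) else 0.0
    # the ring must clear both the layout spread and the buffer radius:
    # a dummy at distance >= 2r from every bin can never clip its disc
    ring_radius = dummy_radius_factor * max(spread, r, 1.0)
    theta = 2.0 * np.pi * np.arange(dummy_count) / dummy_count
    dummies = centroid + ring_radius * np.column_stack(
        [np.cos(theta), np.sin(theta)]
    )
    allpts = np.vstack([pts, dummies])

    cells: list[Polygon] = []
    if len(allpts) >= 4:
        vor = Voronoi(allpts)
        for t in range(len(pts)):
            region = vor.regions[vor.point_region[t]]
            if -1 in region or len(region) < 3:
                cells.append(_halfplane_cell(allpts, t, 2 * ring_radius))
                continue
            verts = vor.vertices[region]
            # convex cell: order vertices by angle for a valid ring
            c = verts.mean(axis=0)
            order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
            cells.append(Polygon(verts[order]))
    else:
        cells = [_halfplane_cell(allpts, t, 2 * ring_radius) for t in range(len(pts))]

    polygons: list[OccupancyPolygon] = []
    for t, bin_index in enumerate(nodes):
        disc = _regular_polygon(pts[t], r, disc_segments)
        occ = cells[t].intersection(disc)
        # snap to a fixed coordinate grid: near-collinear sliver vertices on
        # shared bisectors otherwise trip GEOS overlay robustness downstream
        occ = shapely.set_precision(occ, _COORD_GRID)
        if occ.is_empty or occ.geom_type != "Polygon":
            # degenerate sliver: fall back to the largest polygonal piece
            pieces = [
                g
                for g in getattr(occ, "geoms", [])
                if g.geom_type == "Polygon" and not g.is_empty
            ]
            occ = max(pieces, key=lambda g: g.area) if pieces else Polygon()
        if occ.is_empty:
            ring = np.repeat(pts[t][None, :], 4, axis=0)
            polygons.append(OccupancyPolygon(int(bin_index), ring, 0.0))
            continue
        occ = orient(occ, sign=1.0)  # counter-clockwise exterior
        ring = np.asarray(occ.exterior.coords)
        polygons.append(OccupancyPolygon(int(bin_index), ring, float(occ.area)))
    return GaudiPlot(layout=layout, polygons=polygons)


# --------------------------------------------------------------------------
# rendering


def _color_hex(cmap, frac: float) -> str:
    r, g, b, _ = cmap(float(np.clip(frac, 0.0, 1.0)))
    return f"#{int(r * 255):02x}{int(g * 255):02x}{int(b * 255):02x}"


def render_gaudi(
    plot: GaudiPlot,
    values: np.ndarray,
    highlight: set[int] | None = None,
    out=None,
    tss_bin: int | None = None,
    neighborhood_radius: float | None = None,
    cmap_name: str = "viridis",
    size: int = 640,
) -> str:
    """Render a Gaudi plot as an SVG document string (optionally written to
    ``out``).

    Polygons are filled by a sequential colormap after clipping ``values`` to
    their [1st, 99th] percentile range; NaN bins are grey.  Highlighted bins
    get a dot marker; when a TSS bin and neighborhood radius are given, a
    dashed circle marks the spatial neighborhood used for motif search.
    """
    import matplotlib

    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(plot.polygons):
        raise ValueError(
            f"need one value per polygon: {len(values)} != {len(plot.polygons)}"
        )
    cmap = matplotlib.colormaps[cmap_name]
    finite = values[np.isfinite(values)]
    if len(finite):
        lo, hi = np.percentile(finite, [1, 99])
    else:
        lo, hi = 0.0, 1.0
    span = hi - lo if hi > lo else 1.0

    allv = np.vstack([p.vertices for p in plot.polygons])
    xmin, ymin = allv.min(axis=0)
    xmax, ymax = allv.max(axis=0)
    pad = 0.05 * max(xmax - xmin, ymax - ymin, 1e-9)
    xmin, ymin, xmax, ymax = xmin - pad, ymin - pad, xmax + pad, ymax + pad
    scale = size / max(xmax - xmin, ymax - ymin)

    def sx(x):
        return (x - xmin) * scale

    def sy(y):
        return (ymax - y) * scale  # flip: SVG y grows downward

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    for poly, v in zip(plot.polygons, values):
        if not np.isfinite(v):
            fill = "#bbbbbb"
        else:
            fill = _color_hex(cmap, (np.clip(v, lo, hi) - lo) / span)
        pts = " ".join(
            f"{sx(x):.2f},{sy(y):.2f}" for x, y in poly.vertices[:-1]
        )
        parts.append(
            f'<polygon class="bin" data-bin="{poly.bin_index}" points="{pts}" '
            f'fill="{fill}" stroke="white" stroke-width="0.5"/>'
        )
    node_pos = {p.bin_index: plot.layout.xy[p.bin_index] for p in plot.polygons}
    if tss_bin is not None and neighborhood_radius is not None:
        cx, cy = node_pos[tss_bin]
        parts.append(
            f'<circle class="neighborhood" cx="{sx(cx):.2f}" cy="{sy(cy):.2f}" '
            f'r="{neighborhood_radius * scale:.2f}" fill="none" stroke="black" '
            f'stroke-dasharray="6 4" stroke-width="1.5"/>'
        )
    for b in sorted(highlight or ()):
        cx, cy = node_pos[b]
        parts.append(
            f'<circle class="highlight-dot" cx="{sx(cx):.2f}" cy="{sy(cy):.2f}" '
            f'r="4" fill="green" stroke="black" stroke-width="0.8"/>'
        )
    parts.append("</svg>")
    doc = "\n".join(parts)
    if out is not None:
        with open(out, "w") as fh:
            fh.write(doc)
    return doc


def gaudi_geojson(plot: GaudiPlot, values: np.ndarray | None = None, out=None) -> dict:
    """GeoJSON FeatureCollection of occupancy polygons with bin metadata."""
    grid = plot.layout.grid
    starts = grid.bin_starts
    features = []
    for t, poly in enumerate(plot.polygons):
        props = {
            "bin_index": poly.bin_index,
            "chrom": grid.region.chrom,
            "start": int(starts[poly.bin_index]),
            "area": poly.area,
        }
        if values is not None:
            v = float(values[t])
            props["signal"] = None if not np.isfinite(v) else v
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(map(float, xy)) for xy in poly.vertices]],
                },
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if out is not None:
        with open(out, "w") as fh:
            json.dump(fc, fh)
    return fc
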