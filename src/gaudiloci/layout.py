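"""Kamada-Kawai 2D embedding of the interaction graph.

The layout minimizes the weighted stress

    stress(X) = sum_{i<j} (||x_i - x_j|| - D_ij)^2 / D_ij^2

over all-pairs graph distances D by deterministic gradient descent (L-BFGS)
from a fixed circular initialization ordered by genomic position.  With no
random restarts the embedding is a pure function of D, so repeated runs are
byte-identical.  Layouts are defined up to rigid motion; downstream code uses
only pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .hic import ContactMatrix, InteractionGraph, build_graph, complete_distances
from .regions import BinGrid

__all__ = [
    "SpatialLayout",
    "stress",
    "kamada_kawai_positions",
    "kamada_kawai_layout",
    "compute_layout",
    "mean_interbin_distance",
    "write_layout_tsv",
    "read_layout_tsv",
]


@dataclass
class SpatialLayout:
    """2D coordinates per bin plus the layout's characteristic length scale.

    ``xy`` has one row per grid bin; masked bins carry NaN.  ``mean_interbin``
    is the mean layout distance between genomically consecutive unmasked
    bins — the unit in which buffer and neighborhood radii are expressed.
    """

    grid: BinGrid
    xy: np.ndarray
    mean_interbin: float
    stress: float
    seed: int = 0

    @property
    def nodes(self) -> np.ndarray:
        """Unmasked bin indices (rows of ``xy`` that are finite)."""
        return np.flatnonzero(np.isfinite(self.xy).all(axis=1))


def stress(xy: np.ndarray, D: np.ndarray) -> float:
    """Weighted Kamada-Kawai stress of a configuration against target D."""
    r = pdist(xy)
    d = squareform(D, checks=False)
    return float(np.sum((r - d) ** 2 / d**2))


def _stress_and_grad(flat: np.ndarray, D: np.ndarray) -> tuple[float, np.ndarray]:
    n = D.shape[0]
    xy = flat.reshape(n, 2)
    diff = xy[:, None, :] - xy[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = 2.0 * (r - D) / (D**2 * np.maximum(r, 1e-12))
    np.fill_diagonal(coef, 0.0)
    grad = (coef[:, :, None] * diff).sum(axis=1)
    iu = np.triu_indices(n, k=1)
    val = float(np.sum((r[iu] - D[iu]) ** 2 / D[iu] ** 2))
    return val, grad.ravel()


def _classical_mds_init(D: np.ndarray) -> np.ndarray:
    """Deterministic 2D classical-scaling coordinates for a distance matrix.

    Eigenvector signs are fixed so the result is reproducible across runs.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:2]
    X = V[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
    for c in range(X.shape[1]):
        nz = np.flatnonzero(np.abs(X[:, c]) > 1e-12)
        if len(nz) and X[nz[0], c] < 0:
            X[:, c] = -X[:, c]
    return X


def kamada_kawai_positions(
    D: np.ndarray,
    seed: int = 0,
    jitter: float = 0.0,
    maxiter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Minimize stress for a full distance matrix; returns (xy, final stress).

    Gradient descent (L-BFGS) runs from two deterministic initializations —
    a circle of radius mean(D) visiting nodes in input (genomic) order, and
    classical-MDS coordinates of D — and keeps the lower-stress result; the
    circular start alone can stall in a local minimum on small
    non-realizable metrics.  ``jitter`` optionally perturbs the circular
    start using ``seed`` but is off by default, so the layout is a pure
    function of D.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or not np.all(np.isfinite(D)):
        raise ValueError("D must be a square matrix of finite distances")
    if n == 1:
        return np.zeros((1, 2)), 0.0
    iu = np.triu_indices(n, k=1)
    if np.any(D[iu] <= 0):
        raise ValueError("off-diagonal target distances must be positive")
    radius = float(D[iu].mean())
    theta = 2.0 * np.pi * np.arange(n) / n
    circle = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        circle = circle + rng.normal(0.0, jitter * radius, size=circle.shape)
    best_xy, best_stress = circle, stress(circle, D)
    for init in (circle, _classical_mds_init(D)):
        res = minimize(
            _stress_and_grad,
            init.ravel(),
            args=(D,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
        )
        xy = res.x.reshape(n, 2)
        s = stress(xy, D)
        if s < best_stress:  # strict: ties keep the earlier (circular) result
            best_xy, best_stress = xy, s
    return best_xy, best_stress


def kamada_kawai_layout(
    D: np.ndarray, grid: BinGrid, nodes: np.ndarray | None = None, seed: int = 0
) -> SpatialLayout:
    """Embed the nodes of a distance matrix and assemble a bin-indexed layout."""
    if nodes is None:
        nodes = np.arange(grid.n_bins)
    if len(nodes) != D.shape[0]:
        raise ValueError("one distance-matrix row per node required")
    pos, final = kamada_kawai_positions(D, seed=seed)
    xy = np.full((grid.n_bins, 2), np.nan)
    xy[nodes] = pos
    layout = SpatialLayout(grid, xy, mean_interbin=np.nan, stress=final, seed=seed)
    layout.mean_interbin = mean_interbin_distance(layout)
    return layout


def compute_layout(
    cm: ContactMatrix, top_fraction: float = 0.20, seed: int = 0
) -> tuple[SpatialLayout, InteractionGraph]:
    """Balanced matrix -> interaction graph -> all-pairs distances -> layout."""
    g = build_graph(cm, top_fraction)
    D = complete_distances(g)
    return kamada_kawai_layout(D, cm.grid, nodes=g.nodes, seed=seed), g


def mean_interbin_distance(layout: SpatialLayout) -> float:
    """Mean layout distance between genomically consecutive unmasked bins."""
    nodes = layout.nodes
    if len(nodes) < 2:
        raise ValueError("need at least 2 unmasked bins")
    pts = layout.xy[nodes]
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())


def write_layout_tsv(layout: SpatialLayout, path) -> None:
    g = layout.grid
    starts = g.bin_starts
    with open(path, "w") as fh:
        fh.write("bin_index\tchrom\tstart\tx\ty\n")
        for i in range(g.n_bins):
            x, y = layout.xy[i]
            fh.write(f"{i}\t{g.region.chrom}\t{starts[i]}\t{x:.10g}\t{y:.10g}\n")


def read_layout_tsv(path, grid: BinGrid) -> SpatialLayout:
    xy = np.full((grid.n_bins, 2), np.nan)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("bin_index"):
            raise ValueError(f"{path}: missing layout TSV header")
        for line in fh:
            f = line.split()
            xy[int(f[0])] = (float(f[3]), float(f[4]))
    layout = SpatialLayout(grid, xy, mean_interbin=np.nan, stress=np.nan)
    layout.mean_interbin = mean_interbin_distance(layout)
    return layout
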