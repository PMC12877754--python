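"""Hi-C contact matrices: COO text input, ICE balancing, and the interaction
graph whose inverse-log weights feed the 2D layout.

The balancing step is iterative correction (ICE): bin biases are updated by
``b_i <- b_i * sqrt(s_i / s_mean)`` until the coefficient of variation of the
unmasked row sums falls below tolerance, and the matrix is rescaled so the
mean unmasked row sum is 1 (the convention of standard balanced Hi-C
tooling).  Bins with all-zero rows are masked before iteration and carry NaN
biases.

For the layout graph, balanced interactions are ``log10(1 + x)`` transformed,
the top fraction of nonzero off-diagonal entries is kept, and each kept edge
gets distance ``1 / w``.  Consecutive-bin backbone edges are always added so
the graph is connected (the polymer chain is never broken by sparsity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .regions import BinGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "GraphEdge",
    "InteractionGraph",
    "read_contacts",
    "write_contacts",
    "ice_balance",
    "build_graph",
    "complete_distances",
]


@dataclass
class ContactMatrix:
    """Symmetric binned intrachromosomal contact counts over a window."""

    grid: BinGrid
    values: np.ndarray
    balanced: bool = False
    biases: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = self.grid.n_bins
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("contact values must be non-negative")
        if not np.array_equal(v, v.T):
            raise ValueError("contact matrix must be exactly symmetric")
        self.values = v

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True for masked (all-zero row) bins."""
        return ~self.values.any(axis=1)

    @property
    def unmasked(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)


def read_contacts(path, grid: BinGrid) -> ContactMatrix:
    """Read COO contact text ``chrom1 start1 chrom2 start2 count``.

    Starts must lie on the grid's bin lattice.  Records outside the grid
    (other chromosomes or coordinates beyond the window) are skipped with a
    logged count; duplicate pairs are summed; the matrix is symmetrized by
    mirroring each record across the diagonal.
    """
    n = grid.n_bins
    res = grid.resolution
    origin = grid.region.start
    values = np.zeros((n, n))
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 5:
                raise ValueError(f"{path}:{ln}: expected 5 COO columns")
            c1, s1, c2, s2, cnt = f[0], int(f[1]), f[2], int(f[3]), float(f[4])
            if cnt < 0:
                raise ValueError(f"{path}:{ln}: negative count {cnt}")
            if (
                c1 != grid.region.chrom
                or c2 != grid.region.chrom
                or not grid.region.contains(s1)
                or not grid.region.contains(s2)
            ):
                skipped += 1
                continue
            if (s1 - origin) % res or (s2 - origin) % res:
                raise ValueError(
                    f"{path}:{ln}: start not on the {res} bp bin lattice"
                )
            i, j = (s1 - origin) // res, (s2 - origin) // res
            values[i, j] += cnt
            if i != j:
                values[j, i] += cnt
    if skipped:
        logger.info("read_contacts: skipped %d records outside the grid", skipped)
    return ContactMatrix(grid, values)


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) as COO text."""
    g = cm.grid
    starts = g.bin_starts
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(np.triu(cm.values))):
            fh.write(
                f"{g.region.chrom}\t{starts[i]}\t{g.region.chrom}\t{starts[j]}\t"
                f"{cm.values[i, j]:g}\n"
            )


def ice_balance(
    cm: ContactMatrix, max_iter: int = 200, tol: float = 1e-8
) -> ContactMatrix:
    """Iteratively correct a contact matrix for per-bin biases.

    Returns a new matrix with ``balanced=True``, per-bin biases (NaN for
    masked bins) such that ``out[i, j] * b_i * b_j`` reproduces the input
    exactly, and mean unmasked row sum 1.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    mask = cm.mask
    live = ~mask
    if not live.any():
        raise ValueError("cannot balance a matrix whose rows are all zero")
    x = cm.values[np.ix_(live, live)].copy()
    b = np.ones(x.shape[0])
    converged = False
    for _ in range(max_iter):
        s = x.sum(axis=1)
        sbar = s.mean()
        if np.max(np.abs(s / sbar - 1.0)) < tol:
            converged = True
            break
        f = np.sqrt(s / sbar)
        # rows with zero sum cannot occur here: zero rows were masked upfront
        b *= f
        x /= np.outer(f, f)
    if not converged:
        s = x.sum(axis=1)
        if np.max(np.abs(s / s.mean() - 1.0)) < tol:
            converged = True
        else:
            warnings.warn(
                f"ICE balancing did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
    # rescale so the mean unmasked row sum is exactly 1; fold the scale into
    # the biases so values * b_i * b_j still reproduces the input
    r = x.sum(axis=1).mean()
    x /= r
    b *= np.sqrt(r)
    n = cm.grid.n_bins
    values = np.zeros((n, n))
    values[np.ix_(live, live)] = x
    values = (values + values.T) / 2.0  # shed float asymmetry from the outer divide
    biases = np.full(n, np.nan)
    biases[live] = b
    return ContactMatrix(
        cm.grid, values, balanced=True, biases=biases, converged=converged
    )


@dataclass(frozen=True)
class GraphEdge:
    i: int
    j: int
    weight: float  # log10(1 + balanced value)
    distance: float  # 1 / weight
    backbone: bool = False


@dataclass
class InteractionGraph:
    nodes: np.ndarray  # unmasked bin indices, ascending
    edges: list[GraphEdge] = field(default_factory=list)
    n_candidates: int = 0  # nonzero off-diagonal upper-triangle entries
    n_selected: int = 0    # edges kept by the top-fraction rule


def build_graph(cm: ContactMatrix, top_fraction: float = 0.20) -> InteractionGraph:
    """Select the strongest interactions and attach inverse-log distances.

    Candidates are the nonzero off-diagonal upper-triangle entries among
    unmasked bins; ``k = ceil(top_fraction * M)`` of them with the largest
    ``log10(1 + value)`` are kept (ties broken by ascending ``(i, j)``).
    Backbone edges between genomically consecutive unmasked bins are always
    present; those not selected on their own get the median selected
    distance (1.0 if nothing was selected).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    nodes = cm.unmasked
    if len(nodes) < 2:
        raise ValueError("need at least 2 unmasked bins to build a graph")
    sub = cm.values[np.ix_(nodes, nodes)]
    iu, ju = np.triu_indices(len(nodes), k=1)
    vals = sub[iu, ju]
    nz = vals > 0
    ci, cj, cv = iu[nz], ju[nz], vals[nz]
    m = len(cv)
    k = min(int(np.ceil(top_fraction * m)), m)
    w = np.log10(1.0 + cv)
    # descending weight, then ascending (i, j): lexsort keys are reversed
    order = np.lexsort((cj, ci, -w))
    sel = order[:k]
    edges: dict[tuple[int, int], GraphEdge] = {}
    for t in sel:
        i, j = int(nodes[ci[t]]), int(nodes[cj[t]])
        edges[(i, j)] = GraphEdge(i, j, float(w[t]), float(1.0 / w[t]))
    d_backbone = float(np.median([e.distance for e in edges.values()])) if edges else 1.0
    for a, bnode in zip(nodes[:-1], nodes[1:]):
        key = (int(a), int(bnode))
        if key in edges:
            e = edges[key]
            edges[key] = GraphEdge(e.i, e.j, e.weight, e.distance, backbone=True)
        else:
            edges[key] = GraphEdge(key[0], key[1], 0.0, d_backbone, backbone=True)
    g = InteractionGraph(
        nodes=nodes,
        edges=sorted(edges.values(), key=lambda e: (e.i, e.j)),
        n_candidates=m,
        n_selected=k,
    )
    return g


def complete_distances(g: InteractionGraph) -> np.ndarray:
    """All-pairs shortest-path distances over edge ``d`` values.

    Rows/columns follow ``g.nodes`` order.  The backbone guarantees
    connectivity; a disconnected graph is a hard error.
    """
    n = len(g.nodes)
    idx = {int(b): t for t, b in enumerate(g.nodes)}
    rows, cols, data = [], [], []
    for e in g.edges:
        if e.distance <= 0:
            raise ValueError(f"edge ({e.i},{e.j}) has non-positive distance")
        a, b = idx[e.i], idx[e.j]
        rows += [a, b]
        cols += [b, a]
        data += [e.distance, e.distance]
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    dmat = shortest_path(adj, method="D", directed=False)
    if not np.all(np.isfinite(dmat)):
        raise ValueError("interaction graph is disconnected")
    return dmat
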