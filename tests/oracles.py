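"""Independent oracles used by the acceptance tests.

These deliberately avoid the package's own code paths: the layout oracle is
an exhaustive lattice search, the motif oracle a plain-Python loop scorer.
"""

import math

import numpy as np
from scipy.spatial.distance import cdist

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def layout_suite(seed=0):
    """Fixed random suite of 20 small target-distance matrices
    (4 two-node, 10 three-node, 6 four-node): pairwise distances of random
    planar points, multiplicatively perturbed so some are non-realizable."""
    rng = np.random.default_rng(seed)
    sizes = [2] * 4 + [3] * 10 + [4] * 6
    mats = []
    for n in sizes:
        while True:
            pts = rng.uniform(0, 1, size=(n, 2))
            D = cdist(pts, pts)
            iu = np.triu_indices(n, 1)
            if n == 2 or D[iu].min() >= 0.35:
                break
        pert = rng.uniform(0.95, 1.15, size=(n, n))
        pert = np.triu(pert, 1)
        pert = pert + pert.T + np.eye(n)
        D = D * pert
        D = D / max(D.max(), 1e-9) * rng.uniform(0.8, 1.1)
        np.fill_diagonal(D, 0.0)
        mats.append((D + D.T) / 2)
    return mats


def lattice_minimum_stress(D, step=0.05):
    """Exhaustive minimum of the Kamada-Kawai stress over configurations on
    a square lattice, node 0 pinned at the origin and node 1 on the positive
    x-axis (n <= 4; the 4-node case uses a min-plus decomposition over the
    independent free nodes)."""
    n = D.shape[0]
    extent = 1.25 * D.max()
    xs = np.arange(step, extent + 1e-9, step)
    g = np.arange(-extent, extent + 1e-9, step)
    P = np.array(np.meshgrid(g, g)).reshape(2, -1).T

    def term(dists, d):
        return (dists - d) ** 2 / d**2

    if n == 2:
        return float(term(xs, D[0, 1]).min())
    r0 = np.linalg.norm(P, axis=1)
    if n == 3:
        base = term(r0, D[0, 2])
        best = np.inf
        for x1 in xs:
            t = term(np.linalg.norm(P - [x1, 0.0], axis=1), D[1, 2])
            best = min(best, term(x1, D[0, 1]) + (base + t).min())
        return float(best)
    if n != 4:
        raise ValueError("lattice oracle supports n <= 4 only")
    B = term(cdist(P, P).astype(np.float32), np.float32(D[2, 3]))
    g2 = term(r0, D[0, 2]).astype(np.float32)
    g3 = term(r0, D[0, 3]).astype(np.float32)
    best = np.inf
    for x1 in xs:
        r1 = np.linalg.norm(P - [x1, 0.0], axis=1)
        f2 = g2 + term(r1, D[1, 2]).astype(np.float32)
        f3 = g3 + term(r1, D[1, 3]).astype(np.float32)
        inner = (B + f3[None, :]).min(axis=1)  # best node-3 for each node-2
        best = min(best, term(x1, D[0, 1]) + float((f2 + inner).min()))
    return float(best)


def brute_force_hits(seq, pwm, offset, threshold_fraction):
    """Loop-based PWM scorer over both strands; returns
    {(start, strand, score rounded to 1e-9)}."""
    L = len(pwm)
    lod = [
        [math.log2(pwm.matrix[k, b] / pwm.background[b]) for b in range(4)]
        for k in range(L)
    ]
    max_score = sum(max(row) for row in lod)
    thr = threshold_fraction * max_score
    out = set()
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        rc = "".join(_COMP[b] for b in reversed(window))
        for strand, w in (("+", window), ("-", rc)):
            s = 0.0
            for k, base in enumerate(w):
                if base != "N":
                    s += lod[k][_IDX[base]]
            if s >= thr:
                out.add((offset + pos, strand, round(s, 9)))
    return out
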