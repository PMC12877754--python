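# Methods

This note documents the models, conventions and numerical choices behind
`gaudiloci`, in the order the pipeline applies them, followed by what the
synthetic-data generator does and does not emulate.

## Coordinates and formats

All genomic coordinates are 0-based half-open, everywhere: region strings,
bedGraph, BED, COO contact text, motif hits. Printed genome-browser strings
("chr6:134,835,000-135,835,000", hyphen or en-dash, optional thousands
separators) are parsed under the same convention; whether such printed
ranges are 0- or 1-based is genuinely ambiguous, and at 5 kb bin resolution
the one-base shift is immaterial — we fix half-open 0-based and document it
here. Uncovered bedGraph bases read as 0 (coverage semantics). Canonical
interchange formats are text (COO, bedGraph, FASTA, MEME minimal, JASPAR
PFM, BED, TSV, GeoJSON, SVG); no binary format is required anywhere.

## Contact-matrix balancing (ICE)

Iterative correction removes multiplicative per-bin biases: with row sums
`s_i` over unmasked bins and mean `s̄`, biases update as
`b_i ← b_i·√(s_i/s̄)` and the working matrix is divided by the outer product
of the update factors, until `max_i |s_i/s̄ − 1| < tol` (default 1e-8,
maximum 200 iterations; non-convergence returns a flagged result with a
warning rather than an error). All-zero rows are masked before iteration —
they carry no information and would divide by zero — and keep NaN biases.
The balanced matrix is rescaled so the mean unmasked row sum is exactly 1,
the convention of standard balanced Hi-C tooling; the rescale is folded into
the biases so `out_ij·b_i·b_j` reproduces the input exactly, which is also
the invariant the tests check.

## Interaction graph

Candidates are the nonzero off-diagonal upper-triangle entries among
unmasked bins. Interactions are transformed as `w = log10(1 + x)` rather
than `log10(x)`: balanced entries are ≤ 1 almost everywhere, so a bare log
would produce non-positive weights and negative or infinite inverse
distances; the +1 keeps `d = 1/w` finite and positive while preserving the
ranking. "Top 20%" means `k = ceil(0.20·M)` of the M nonzero candidates —
counting structural zeros would make k depend on sparsity artifacts. Ties at
the cutoff break by ascending `(i, j)` so output is deterministic. Backbone
edges between genomically consecutive unmasked bins are always added
(distance = median selected distance, or 1.0 when nothing is selected):
chromatin is a polymer, and the chain also guarantees the connectivity the
all-pairs shortest-path step (Dijkstra over edge distances) requires.

## Kamada–Kawai layout

The embedding minimizes weighted stress
`Σ_{i<j} (‖x_i−x_j‖ − D_ij)²/D_ij²` by L-BFGS with an analytic gradient,
initialized on a circle of radius mean(D) visiting bins in genomic order.
There are no random restarts by default (the seed is reserved for optional
jitter), so a layout is a pure function of its distance matrix and repeated
runs are byte-identical; if descent ever fails to improve on the
initialization, the initialization is returned. Layouts are defined only up
to rigid motion — everything downstream uses pairwise distances, never
absolute coordinates. The characteristic length unit is the *mean interbin
distance*: the mean layout distance between genomically consecutive unmasked
bins.

## Gaudí geometry

Each unmasked bin's spatial occupancy is its Voronoi cell intersected with a
buffer disc of radius 1.5× the mean interbin distance centered on the bin.
We read "buffer zone (1.5 the mean interbin distance)" as a radius, not a
diameter, and buffer the point before clipping by the cell, following the
order of operations that definition implies. Implementation choices:

- The Voronoi diagram is computed over the bins plus 36 dummy points equally
  spaced on a ring centered at the layout centroid, which closes all cells.
  The ring radius is 4× the largest of (layout spread, buffer radius, 1.0):
  including the buffer radius in the floor guarantees a dummy point is at
  least twice the buffer radius from every bin, so dummy cells can never
  clip a buffer disc (a single-bin layout would otherwise lose disc area).
- Discs are regular 64-gons, so all geometry is exact polygon–polygon
  intersection; the ≤ 0.17% area deficit of the 64-gon is far below every
  test tolerance.
- Occupancy polygons are snapped to a 1e-9 coordinate grid after clipping.
  Cells that share a bisector edge otherwise end up with near-collinear
  sliver vertices that can trigger asymmetric overlay results in the
  underlying geometry engine (an intersection reported as the whole of one
  polygon in one argument order and empty in the other); snapping makes all
  downstream area computations robust. 1e-9 layout units is ~9 orders of
  magnitude below any bin spacing.
- Coincident bin coordinates (from degenerate toy inputs) are separated by a
  deterministic jitter of 1e-6× the mean interbin distance and logged, not
  rejected.

Rendering clips signal values to their [1st, 99th] percentile before
colormapping (outliers otherwise flatten the scale), paints NaN bins grey,
marks highlighted bins with a dot and draws a dashed circle at the
neighborhood radius around a designated TSS bin.

## TSS neighborhood and contribution filtering

The neighborhood of a TSS is every unmasked bin whose layout position lies
within 3.0× the mean interbin distance of the TSS-containing bin (inclusive
radius) — spatial proximity, not genomic. Contribution scores are filtered
per analysis window and per condition: the retention threshold is the 0.90
quantile (numpy linear interpolation) of per-base scores across the whole
window, since no better-defined reference distribution is available at desk
scale. A base is retained when its score is ≥ the threshold *and strictly
positive*, and falls inside a neighborhood bin; retained bases merge into
maximal intervals. The positivity requirement is deliberate: contribution
tracks are sparse, often mostly zero, and the window quantile of such a
track is 0 — under a bare ≥ rule every zero-contribution base would count as
"high-contribution", which inverts the meaning of the filter. Zero-score
bases are never top contributors. An all-zero track yields an empty result
with a warning.

## Motif scanning, families, enrichment

Scanning scores every window on both strands by summed `log2(p/background)`
log-odds; minus-strand windows are scored on the reverse complement and
reported in plus-strand coordinates. `N` contributes 0, so masked flanks
neither create nor destroy hits. A window is a hit when its score reaches
`pwm_score_fraction` (default 0.8) of the motif's maximum attainable
log-odds — a deterministic, oracle-checkable threshold that avoids a score
null model. MEME probability rows are pseudocount-regularized only when
they contain zeros (otherwise log-odds diverge); JASPAR counts always get a
per-cell pseudocount of 0.01, `(c + p)/(Σc + 4p)`, which keeps log-odds
finite without distorting strong positions.

Within a TF family (AP1 = FOS/FOSB/FOSL1/FOSL2/JUN/JUNB/JUND; TCF/LEF =
TCF7/TCF7L1/TCF7L2/LEF1; names with database suffixes are matched by leading
token, unmapped names become their own family), hits overlapping by at least
one base — either strand — collapse to one site, so a footprint bound by
several paralogous motifs is counted once. The differential report compares
collapsed per-family site counts between two conditions analyzed over the
same grid, sorted by |delta|, and aligns overlapping sites across conditions
so "open in A, closed in B" sites are directly listable.

Sequence-set motif enrichment is a per-motif 2×2 Fisher exact test (two-sided)
on sequence-level hit presence, foreground vs background, with
Benjamini–Hochberg q-values, ranked by ascending q then descending sample
odds ratio `(a·d)/(b·c)`. This is a deliberate simplification of a dedicated
motif-enrichment tool's positional statistics: it keeps the q < 0.01
filtering convention and ranking semantics while remaining exactly testable
against an enumerated hypergeometric oracle. A motif hitting no sequence
anywhere reports p = 1 and odds ratio 1 (degenerate-table convention).

## Synthetic data

The generator produces inputs with the statistical structure the analysis
assumes, at the analysis scale (1 Mb window, 5 kb bins, 200 bins):

- **Hi-C**: expected counts `depth·(1+|i−j|)^(−α)`, α = 1.0 (the canonical
  contact-decay slope), times a within-TAD boost of 3.0 — strong enough that
  TAD co-membership dominates the spatial neighborhood, which is the
  property the analysis exploits; optional Poisson sampling of the upper
  triangle, mirrored so matrices stay exactly symmetric. Sequencing depth
  default 100 expected counts on the diagonal.
- **Genome**: i.i.d. background at GC 0.42 (typical mammalian) with consensus
  sites written at chosen positions (reverse-complemented on the minus
  strand). AP1 consensus TGACTCA, TCF/LEF consensus CTTTGTT (canonical
  cores), both configurable.
- **Tracks**: ATAC = basal 0.5 + 5.0 over peak bins + optional truncated
  Gaussian noise; contribution = triangular bumps of height 1 spanning each
  accessible site ± 5 bp — a footprint-like shape whose core exceeds any
  quantile threshold before its flanks.
- **Condition pair**: one shared genome and shared TADs; six AP1 sites in
  the bins around locus E are peak/bumped only in condition A, five TCF/LEF
  sites around locus L only in condition B, mirroring a vehicle-vs-treatment
  design in which MAPK-driven AP1 occupancy is lost and WNT-driven TCF/LEF
  occupancy gained upon treatment.

All generators are pure functions of configuration and seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: read-level noise and mappability artifacts, ligation
biases beyond multiplicative per-bin factors, realistic motif degeneracy and
clustering, co-accessibility correlation structure, condition-dependent TAD
rearrangement, and contribution-score noise from model training. End-to-end
recovery on this generator demonstrates the pipeline's plumbing and the
correctness of each stage's contract, not the biological error rate of the
analysis on sequencing data.

## Problem sizes and tolerances

Acceptance-level checks run at the analysis scale (200-bin windows) with 20
noise-free and 20 noisy simulated condition pairs; kernel checks use 100×100
random matrices for balancing (row-sum CV < 1e-6, reconstruction rtol 1e-6),
an exhaustive 0.05-step lattice search as the layout oracle on ≤ 4 nodes
(final stress ≤ 1.05× the lattice minimum; the min-plus decomposition over
the two free nodes makes the 4-node enumeration tractable), the circle–slab
closed form for geometry (0.5%, dominated by the 64-gon deficit), and exact
agreement with a loop-based scorer for motif scanning. The noisy end-to-end
condition (Poisson Hi-C, ATAC noise at 0.2× peak height) is expected to
recover correct delta signs in ≥ 18 of 20 runs; the noise perturbs the
layout and hence neighborhood membership, not the planted truth.

## Known limitations

- The layout optimizer is a local method; for pathological distance
  matrices a lower-stress embedding may exist. The lattice oracle bounds
  this only for tiny instances.
- The contribution-quantile reference distribution (whole window, per
  condition) is a documented choice; per-region-set or genome-wide
  references would shift thresholds.
- Family collapsing counts unique sites, not per-member hits; a site bound
  by two families counts once in each.
- Enrichment treats sequences as exchangeable units and ignores hit
  multiplicity per sequence.
- Single window, single chromosome: genome-wide tiling, TAD calling and
  compartment analysis are out of scope.
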