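import numpy as np
import pytest

from gaudiloci import (
    GenomicRegion,
    SignalTrack,
    bin_signal,
    differential_occupancy,
    high_contribution_intervals,
    make_bin_grid,
    tss_neighborhood,
)
from gaudiloci.analysis import write_arcs_tsv, write_report_tsv
from gaudiloci.motifs import MotifHit


# ---------------------------------------------------------------- bin_signal


def test_constant_track_mean(small_grid):
    region = small_grid.region
    track = SignalTrack(region, [region.start], [region.end], [2.5])
    assert np.allclose(bin_signal(track, small_grid, "mean"), 2.5)


def test_sum_conserves_integral(small_grid):
    rng = np.random.default_rng(0)
    dense = rng.uniform(0, 3, size=len(small_grid.region))
    track = SignalTrack.from_dense(small_grid.region, dense)
    sums = bin_signal(track, small_grid, "sum")
    assert sums.sum() == pytest.approx(track.integral(), abs=1e-9)


def test_half_covered_bin_mean(small_grid):
    track = SignalTrack(small_grid.region, [0], [2500], [1.0])
    means = bin_signal(track, small_grid, "mean")
    assert means[0] == pytest.approx(0.5)
    assert np.all(means[1:] == 0.0)


def test_max_stat_sees_uncovered_zero(small_grid):
    track = SignalTrack(small_grid.region, [0], [2500], [-2.0])
    assert bin_signal(track, small_grid, "max")[0] == 0.0


def test_track_must_cover_grid(small_grid):
    short = SignalTrack(GenomicRegion("chr1", 0, 10_000), [0], [10], [1.0])
    with pytest.raises(ValueError):
        bin_signal(short, small_grid)
    with pytest.raises(ValueError):
        bin_signal(SignalTrack.empty(small_grid.region), small_grid, "median")


# ------------------------------------------------------------ neighborhoods


def test_collinear_neighborhood_seven_members(collinear_layout):
    # need a wider line so tss +/- 3 exists: build 9 collinear bins
    import gaudiloci

    grid = make_bin_grid(GenomicRegion("chr1", 0, 45_000), 5000)
    xy = np.column_stack([np.arange(9, dtype=float), np.zeros(9)])
    lay = gaudiloci.SpatialLayout(grid, xy, mean_interbin=1.0, stress=0.0)
    sel = tss_neighborhood(lay, 4, neighborhood_factor=3.0)
    assert sel.member_bins.tolist() == [1, 2, 3, 4, 5, 6, 7]  # tss +/- 3
    assert sel.radius == pytest.approx(3.0)
    # adjacent member bins merge into one genomic interval
    assert [(r.start, r.end) for r in sel.member_regions] == [(5000, 40_000)]


def test_zero_factor_neighborhood_is_tss_only(collinear_layout):
    sel = tss_neighborhood(collinear_layout, 2, neighborhood_factor=1e-12)
    assert sel.member_bins.tolist() == [2]
    assert sel.tss_bin == 2


def test_large_factor_includes_all_bins(collinear_layout):
    sel = tss_neighborhood(collinear_layout, 0, neighborhood_factor=100.0)
    assert sel.member_bins.tolist() == [0, 1, 2, 3, 4]


def test_masked_tss_bin_rejected(collinear_layout):
    collinear_layout.xy[1] = np.nan
    with pytest.raises(ValueError):
        tss_neighborhood(collinear_layout, 1)


def test_arcs_table_lists_each_member_once(collinear_layout, tmp_path):
    sel = tss_neighborhood(collinear_layout, 2, neighborhood_factor=1.0)
    p = tmp_path / "arcs.tsv"
    write_arcs_tsv(sel, collinear_layout.grid, p)
    lines = p.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["tss_bin", "tss_start", "member_bin", "member_start"]
    members = [int(l.split("\t")[2]) for l in lines[1:]]
    assert members == [1, 3]  # tss itself excluded


# ----------------------------------------------------- contribution filter


def region10():
    return GenomicRegion("chr1", 0, 10)


def full_selection(window, resolution=5):
    """A selection whose member regions span the whole window."""
    from gaudiloci.analysis import NeighborhoodSelection

    grid = make_bin_grid(window, resolution)
    return NeighborhoodSelection(
        tss_bin=0,
        radius=1.0,
        member_bins=np.arange(grid.n_bins),
        member_regions=[window],
    )


def test_quantile_rule_selects_only_top_base():
    """Scores 1..10 at quantile 0.9: the linear-interpolation quantile is
    9.1, so only the score-10 base is retained."""
    w = region10()
    track = SignalTrack.from_dense(w, np.arange(1.0, 11.0))
    out = high_contribution_intervals(track, w, 0.9, full_selection(w))
    assert [(r.start, r.end) for r in out] == [(9, 10)]


def test_equal_scores_all_retained():
    w = region10()
    track = SignalTrack.from_dense(w, np.full(10, 2.0))
    out = high_contribution_intervals(track, w, 0.9, full_selection(w))
    assert [(r.start, r.end) for r in out] == [(0, 10)]


def test_all_zero_track_warns_and_empty():
    w = region10()
    with pytest.warns(RuntimeWarning):
        out = high_contribution_intervals(
            SignalTrack.empty(w), w, 0.9, full_selection(w)
        )
    assert out == []


def test_neighborhood_excludes_top_base():
    from gaudiloci.analysis import NeighborhoodSelection

    w = region10()
    track = SignalTrack.from_dense(w, np.arange(1.0, 11.0))
    sel = NeighborhoodSelection(
        tss_bin=0,
        radius=1.0,
        member_bins=np.array([0]),
        member_regions=[GenomicRegion("chr1", 0, 5)],
    )
    out = high_contribution_intervals(track, w, 0.5, sel)
    # threshold = quantile(1..10, 0.5) = 5.5 -> bases with 6..10, clipped to [0,5)
    assert out == []
    sel2 = NeighborhoodSelection(
        tss_bin=0,
        radius=1.0,
        member_bins=np.array([0]),
        member_regions=[GenomicRegion("chr1", 0, 8)],
    )
    out2 = high_contribution_intervals(track, w, 0.5, sel2)
    assert [(r.start, r.end) for r in out2] == [(5, 8)]


def test_adjacent_retained_bases_merge_and_count_exact():
    w = GenomicRegion("chr1", 0, 20)
    dense = np.zeros(20)
    dense[[3, 4, 5, 9, 15]] = [5.0, 6.0, 7.0, 9.0, 9.0]
    track = SignalTrack.from_dense(w, dense)
    out = high_contribution_intervals(track, w, 0.75, full_selection(w, 10))
    threshold = np.quantile(dense, 0.75)
    expected_count = int(((dense >= threshold) & (dense > 0)).sum())
    assert sum(len(r) for r in out) == expected_count
    # merging is idempotent: intervals are disjoint and non-adjacent
    for a, b in zip(out, out[1:]):
        assert a.end < b.start


def test_bad_quantile_rejected():
    w = region10()
    t = SignalTrack.from_dense(w, np.ones(10))
    with pytest.raises(ValueError):
        high_contribution_intervals(t, w, 1.0, full_selection(w))


# ------------------------------------------------------------- differential


def _hit(name, start, end=None, chrom="chr1"):
    end = end if end is not None else start + 7
    return MotifHit(name, chrom, start, end, "+", 5.0, 0.9)


def test_report_formats_printed_counts():
    """Six AP1 sites in condition A vs three in B -> row (AP1, 6, 3, +3)."""
    hits_a = [_hit("JUNB", 100 * i) for i in range(6)]
    hits_b = [_hit("FOSL1", 100 * i) for i in range(3)]
    rep = differential_occupancy(hits_a, hits_b, "vehicle", "treated")
    (row,) = rep.rows
    assert (row.family, row.count_a, row.count_b, row.delta) == ("AP1", 6, 3, 3)
    df = rep.to_dataframe()
    assert df.loc[0, "count_vehicle"] == 6 and df.loc[0, "delta"] == 3
    # sites open in A and closed in B are listable
    a_only = [s for s, in_a, in_b in row.sites if in_a and not in_b]
    assert len(a_only) == 3


def test_identical_conditions_zero_delta():
    hits = [_hit("JUNB", 0), _hit("TCF7", 500)]
    rep = differential_occupancy(hits, list(hits))
    assert all(r.delta == 0 for r in rep.rows)


def test_family_only_in_second_condition():
    rep = differential_occupancy([], [_hit("LEF1", 0), _hit("TCF7", 100)])
    (row,) = rep.rows
    assert (row.family, row.count_a, row.count_b, row.delta) == ("TCF/LEF", 0, 2, -2)


def test_rows_sorted_by_absolute_delta():
    hits_a = [_hit("JUNB", 100 * i) for i in range(5)] + [_hit("GATA1", 9000)]
    hits_b = [_hit("TCF7", 100 * i) for i in range(2)] + [_hit("GATA1", 9000)]
    rep = differential_occupancy(hits_a, hits_b)
    assert [r.family for r in rep.rows] == ["AP1", "TCF/LEF", "GATA1"]


def test_swapping_conditions_negates_deltas():
    hits_a = [_hit("JUNB", 0), _hit("JUND", 300)]
    hits_b = [_hit("TCF7", 600)]
    fwd = differential_occupancy(hits_a, hits_b)
    rev = differential_occupancy(hits_b, hits_a)
    fwd_d = {r.family: r.delta for r in fwd.rows}
    rev_d = {r.family: r.delta for r in rev.rows}
    assert fwd_d == {f: -d for f, d in rev_d.items()}


def test_report_tsv_layout(tmp_path):
    rep = differential_occupancy([_hit("JUNB", 0)], [], "A", "B")
    p = tmp_path / "report.tsv"
    write_report_tsv(rep, p)
    header, row = p.read_text().strip().splitlines()
    assert header.split("\t") == ["tf_family", "count_A", "count_B", "delta", "sites"]
    assert row.split("\t")[:4] == ["AP1", "1", "0", "1"]
    assert "chr1:0-7[A]" in row
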