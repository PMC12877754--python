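import math

import numpy as np
import pytest

from gaudiloci import PWM, count_hits_by_family, motif_enrichment, scan_pwm
from gaudiloci.motifs import (
    MotifHit,
    collapse_hits_by_family,
    family_of,
    read_hits_bed,
    write_hits_bed,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_scores(seq: str, pwm: PWM) -> dict[str, list[float]]:
    """Independent per-window log-odds scorer (plain Python loops).

    Plus strand scores the window directly; minus strand scores the
    reverse complement of the window against the motif.
    """
    L = len(pwm)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = {"+": [], "-": []}
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        rc = "".join(_COMP[b] for b in reversed(window))
        for strand, w in (("+", window), ("-", rc)):
            s = 0.0
            for k, base in enumerate(w):
                if base == "N":
                    continue
                s += math.log2(pwm.matrix[k, idx[base]] / pwm.background[idx[base]])
            out[strand].append(s)
    return out


def hits_from_scores(scores, pwm, offset, threshold_fraction):
    thr = threshold_fraction * pwm.max_score()
    expected = set()
    for strand in "+-":
        for pos, s in enumerate(scores[strand]):
            if s >= thr:
                expected.add((offset + pos, strand, round(s, 9)))
    return expected


# ---------------------------------------------------------------- scanning


def test_consensus_hit_found_at_planted_position():
    pwm = PWM.from_consensus("M", "ACGT")
    hits = scan_pwm("TTTTACGTTTTT", 100, pwm, score_fraction_threshold=0.9,
                    both_strands=False)
    assert [(h.start, h.end, h.strand) for h in hits] == [(104, 108, "+")]
    assert hits[0].score_fraction == pytest.approx(1.0)


def test_minus_strand_hit_reported_in_plus_coordinates():
    pwm = PWM.from_consensus("M", "AACC")
    hits = scan_pwm("TTGGTT", 50, pwm, score_fraction_threshold=0.9)
    assert [(h.start, h.strand) for h in hits] == [(52, "-")]


def test_threshold_one_without_consensus_is_empty():
    pwm = PWM.from_consensus("M", "ACGTACGT")
    assert scan_pwm("ACGTACGA" * 3, 0, pwm, score_fraction_threshold=1.0) == []


def test_motif_longer_than_sequence_is_empty_not_error():
    pwm = PWM.from_consensus("M", "ACGTACGT")
    assert scan_pwm("ACG", 0, pwm) == []


def test_invalid_characters_rejected():
    pwm = PWM.from_consensus("M", "ACGT")
    with pytest.raises(ValueError):
        scan_pwm("ACXT", 0, pwm)


def test_n_bases_contribute_zero():
    """Flanking Ns neither create nor destroy a hit; an N inside a window
    scores exactly the sum of its non-N positions."""
    pwm = PWM.from_consensus("M", "ACGT", match_prob=0.85)
    clean = scan_pwm("ACGT", 0, pwm, 0.99, both_strands=False)
    flanked = scan_pwm("NNACGTNN", 0, pwm, 0.99, both_strands=False)
    assert [(h.start - 2, h.score) for h in flanked] == [
        (h.start, h.score) for h in clean
    ]
    lod_match = math.log2(0.85 / 0.25)
    [hit] = scan_pwm("ANGT", 0, pwm, 0.5, both_strands=False)
    assert hit.score == pytest.approx(3 * lod_match)


@pytest.mark.parametrize("seed", range(5))
def test_scan_matches_brute_force_on_random_sequences(seed):
    """Vectorized scanner agrees exactly with the loop-based oracle."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                             size=300))
    probs = rng.dirichlet(np.full(4, 0.6), size=rng.integers(4, 9))
    pwm = PWM.from_probabilities(f"R{seed}", probs)
    scores = brute_force_scores(seq, pwm)
    expected = hits_from_scores(scores, pwm, 10, 0.7)
    got = {
        (h.start, h.strand, round(h.score, 9))
        for h in scan_pwm(seq, 10, pwm, 0.7)
    }
    assert got == expected


def test_raising_threshold_never_adds_hits():
    rng = np.random.default_rng(12)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    pwm = PWM.from_probabilities("M", rng.dirichlet(np.full(4, 0.5), size=6))
    counts = [
        len(scan_pwm(seq, 0, pwm, thr)) for thr in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------- families


def test_family_mapping_and_fallback(caplog):
    assert family_of("JUNB") == "AP1"
    assert family_of("FOSL1_MOUSE.H11MO.0.A") == "AP1"
    assert family_of("TCF7L2") == "TCF/LEF"
    assert family_of("GATA1") == "GATA1"  # unmapped -> own name


def _hit(name, start, end, strand="+", chrom="chr1"):
    return MotifHit(name, chrom, start, end, strand, 5.0, 0.9)


def test_same_footprint_collapses_to_one_site():
    hits = [_hit("FOSL1", 100, 107), _hit("JUNB", 100, 107, "-")]
    assert count_hits_by_family(hits) == {"AP1": 1}


def test_disjoint_sites_counted_separately():
    hits = [_hit("TCF7L2", 100, 107), _hit("TCF7L2", 200, 207)]
    assert count_hits_by_family(hits) == {"TCF/LEF": 2}


def test_touching_sites_do_not_merge():
    # half-open intervals: [100,107) and [107,114) share no base
    hits = [_hit("JUN", 100, 107), _hit("JUN", 107, 114)]
    assert count_hits_by_family(hits) == {"AP1": 2}


def test_empty_hit_list_empty_counts():
    assert count_hits_by_family([]) == {}


def test_collapse_merges_chains_of_overlaps():
    hits = [_hit("JUN", 0, 7), _hit("FOS", 5, 12), _hit("JUNB", 11, 18)]
    sites = collapse_hits_by_family(hits)["AP1"]
    assert [(s.start, s.end) for s in sites] == [(0, 18)]


# ---------------------------------------------------------------- enrichment


def fisher_two_sided(a, fg_n, bg_with, bg_n):
    """Exact two-sided Fisher p by hypergeometric enumeration: sum the
    probabilities of every table at least as extreme (pmf <= pmf observed),
    independent of scipy."""
    K = a + bg_with          # total sequences with a hit
    N = fg_n + bg_n
    n = fg_n

    def comb(n_, k_):
        return math.comb(n_, k_) if 0 <= k_ <= n_ else 0

    total = comb(N, n)
    pmf = {x: comb(K, x) * comb(N - K, n - x) / total for x in range(0, min(K, n) + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_enrichment_odds_ratio_and_fisher_p():
    """8/10 fg vs 1/10 bg: sample OR = (8*9)/(2*1) = 36; p matches the
    hypergeometric tail computed by exact enumeration."""
    pwm = PWM.from_consensus("M", "ACGTAC")
    with_hit = "TTTACGTACTTT"
    without = "TTTTTTTTTTTT"
    fg = {f"f{i}": with_hit if i < 8 else without for i in range(10)}
    bg = {f"b{i}": with_hit if i < 1 else without for i in range(10)}
    df = motif_enrichment(fg, bg, [pwm], 0.9)
    row = df.iloc[0]
    assert row["fg_with_hit"] == 8 and row["bg_with_hit"] == 1
    assert row["odds_ratio"] == pytest.approx(36.0)
    assert row["p"] == pytest.approx(fisher_two_sided(8, 10, 1, 10), rel=1e-9)
    assert row["q"] == pytest.approx(row["p"])  # single motif: BH is identity


def test_enrichment_identical_sets_null():
    pwm = PWM.from_consensus("M", "ACGTAC")
    seqs = {"a": "TTTACGTACTTT", "b": "TTTTTTTTTTTT"}
    df = motif_enrichment(seqs, dict(seqs), [pwm], 0.9)
    assert df.iloc[0]["odds_ratio"] == pytest.approx(1.0)
    assert df.iloc[0]["p"] == pytest.approx(1.0)


def test_enrichment_absent_motif_degenerate():
    pwm = PWM.from_consensus("M", "ACGTACGTAC")
    seqs = {"a": "TTTTTTTTTTTT"}
    df = motif_enrichment(seqs, dict(seqs), [pwm], 0.9)
    assert df.iloc[0]["p"] == 1.0 and df.iloc[0]["odds_ratio"] == 1.0


def test_enrichment_q_monotone_in_p():
    rng = np.random.default_rng(3)
    pwms = [
        PWM.from_probabilities(f"M{i}", rng.dirichlet(np.full(4, 0.7), size=5))
        for i in range(6)
    ]
    fg = {f"f{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(8)}
    bg = {f"b{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(8)}
    df = motif_enrichment(fg, bg, pwms, 0.75)
    by_p = df.sort_values("p")
    assert by_p["q"].is_monotonic_increasing
    with pytest.raises(ValueError):
        motif_enrichment({}, bg, pwms)


# ---------------------------------------------------------------- hits BED


def test_hits_bed_round_trip(tmp_path):
    hits = [
        MotifHit("JUNB", "chr1", 100, 107, "+", 6.5, 0.91),
        MotifHit("TCF7", "chr1", 50, 57, "-", 5.0, 0.85),
    ]
    p = tmp_path / "hits.bed"
    write_hits_bed(hits, p)
    back = read_hits_bed(p)
    assert [(h.motif_name, h.start, h.end, h.strand) for h in back] == [
        ("TCF7", 50, 57, "-"),
        ("JUNB", 100, 107, "+"),
    ]
    assert back[0].score_fraction == pytest.approx(0.85)
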