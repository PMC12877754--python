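"""PWM motif scanning, TF-family collapsing, and Fisher-exact enrichment.

Scanning scores every window of a sequence (both strands) by summed
``log2(p/background)`` log-odds; ``N`` bases contribute 0 so masked flanks
neither create nor destroy hits.  A window is a hit when its score reaches a
configurable fraction of the motif's maximum attainable log-odds — a
deterministic threshold that needs no score-distribution model.

Family collapsing merges overlapping hits of paralogous motifs (e.g. all
JUN/FOS members) into unique binding sites, so one footprint bound by several
family members is counted once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .pwm import PWM
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "DEFAULT_FAMILY_MAP",
    "scan_pwm",
    "scan_pwms",
    "family_of",
    "collapse_hits_by_family",
    "count_hits_by_family",
    "motif_enrichment",
    "write_hits_bed",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# AP1 = JUN/FOS dimer family; TCF/LEF = WNT effector family
DEFAULT_FAMILY_MAP: dict[str, str] = {
    **{m: "AP1" for m in ("FOS", "FOSB", "FOSL1", "FOSL2", "JUN", "JUNB", "JUND")},
    **{m: "TCF/LEF" for m in ("TCF7", "TCF7L1", "TCF7L2", "LEF1")},
}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    chrom: str
    start: int  # 0-based, plus-strand coordinates
    end: int
    strand: str  # "+" or "-"
    score: float  # log-odds (log2)
    score_fraction: float  # score / motif maximum


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as err:
        raise ValueError(f"invalid sequence character {err.args[0]!r}") from None


def scan_pwm(
    seq: str,
    offset: int,
    pwm: PWM,
    score_fraction_threshold: float = 0.8,
    both_strands: bool = True,
    chrom: str = ".",
) -> list[MotifHit]:
    """Scan ``seq`` (genomic start ``offset``) for windows scoring at least
    ``score_fraction_threshold`` times the motif's maximum log-odds.

    Minus-strand windows are scored on the reverse complement and reported in
    plus-strand coordinates.  A motif longer than the sequence yields an
    empty list.
    """
    seq = seq.upper()
    codes = _encode(seq)
    L = len(pwm)
    if L > len(codes):
        return []
    max_score = pwm.max_score()
    if max_score <= 0:
        warnings.warn(
            f"motif {pwm.name!r} has non-positive maximum log-odds; no hits reported",
            RuntimeWarning,
            stacklevel=2,
        )
        return []
    thr = score_fraction_threshold * max_score
    lod = np.column_stack([pwm.log_odds(), np.zeros(L)])  # N column scores 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    strands = [("+", lod)]
    if both_strands:
        # scoring a window against the position- and base-reversed log-odds
        # equals scoring its reverse complement against the original motif
        strands.append(("-", np.column_stack([lod[::-1, :4][:, ::-1], np.zeros(L)])))
    hits: list[MotifHit] = []
    pos_idx = np.arange(L)
    for strand, mat in strands:
        scores = mat[pos_idx, windows].sum(axis=1)
        for pos in np.flatnonzero(scores >= thr):
            s = float(scores[pos])
            hits.append(
                MotifHit(
                    pwm.name,
                    chrom,
                    offset + int(pos),
                    offset + int(pos) + L,
                    strand,
                    s,
                    min(max(s / max_score, 0.0), 1.0),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_pwms(
    seq: str,
    offset: int,
    pwms: list[PWM],
    score_fraction_threshold: float = 0.8,
    both_strands: bool = True,
    chrom: str = ".",
) -> list[MotifHit]:
    out: list[MotifHit] = []
    for p in pwms:
        out.extend(
            scan_pwm(seq, offset, p, score_fraction_threshold, both_strands, chrom)
        )
    return out


def family_of(motif_name: str, family_map: dict[str, str] | None = None) -> str:
    """TF family of a motif name; unmapped names fall back to themselves.

    Database-style names such as ``JUNB_MOUSE.H11MO.0.A`` are matched by
    their leading token.
    """
    fam_map = DEFAULT_FAMILY_MAP if family_map is None else family_map
    if motif_name in fam_map:
        return fam_map[motif_name]
    token = motif_name.split("_")[0].split(".")[0].upper()
    if token in fam_map:
        return fam_map[token]
    logger.info("motif %r not in family map; counted as its own family", motif_name)
    return motif_name


def collapse_hits_by_family(
    hits: list[MotifHit], family_map: dict[str, str] | None = None
) -> dict[str, list[GenomicRegion]]:
    """Merge overlapping hits (any shared base, either strand) within each
    family into unique sites."""
    by_family: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_family.setdefault(family_of(h.motif_name, family_map), []).append(h)
    sites: dict[str, list[GenomicRegion]] = {}
    for fam, fam_hits in sorted(by_family.items()):
        fam_hits.sort(key=lambda h: (h.chrom, h.start, h.end))
        merged: list[GenomicRegion] = []
        for h in fam_hits:
            if (
                merged
                and h.chrom == merged[-1].chrom
                and h.start < merged[-1].end
            ):
                merged[-1] = GenomicRegion(
                    h.chrom, merged[-1].start, max(merged[-1].end, h.end)
                )
            else:
                merged.append(GenomicRegion(h.chrom, h.start, h.end))
        sites[fam] = merged
    return sites


def count_hits_by_family(
    hits: list[MotifHit], family_map: dict[str, str] | None = None
) -> dict[str, int]:
    """Unique-site count per TF family (overlap-collapsed)."""
    return {f: len(s) for f, s in collapse_hits_by_family(hits, family_map).items()}


def motif_enrichment(
    fg: dict[str, str],
    bg: dict[str, str],
    pwms: list[PWM],
    score_fraction_threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-motif 2x2 Fisher exact test on sequence-level hit presence.

    For each motif the table is (foreground sequences with >= 1 hit vs
    without) against the same split in the background; p-values are
    Benjamini-Hochberg corrected and rows ranked by ascending q, then
    descending sample odds ratio.  This is a sequence-set enrichment screen,
    not a positional model.
    """
    if not fg or not bg:
        raise ValueError("foreground and background sequence sets must be non-empty")
    rows = []
    for pwm in pwms:
        fg_with = sum(
            bool(scan_pwm(s, 0, pwm, score_fraction_threshold)) for s in fg.values()
        )
        bg_with = sum(
            bool(scan_pwm(s, 0, pwm, score_fraction_threshold)) for s in bg.values()
        )
        a, b = fg_with, len(fg) - fg_with
        c, d = bg_with, len(bg) - bg_with
        if a + c == 0:  # motif absent everywhere: degenerate table
            odds, p = 1.0, 1.0
        else:
            if b * c == 0:
                odds = np.inf if a * d > 0 else 1.0
            else:
                odds = (a * d) / (b * c)
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((pwm.name, a, c, odds, p))
    df = pd.DataFrame(
        rows, columns=["motif", "fg_with_hit", "bg_with_hit", "odds_ratio", "p"]
    )
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(
        ["q", "odds_ratio"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return df


def read_hits_bed(path) -> list[MotifHit]:
    """Read BED6 hits written by :func:`write_hits_bed` (log-odds not kept)."""
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 BED columns")
            hits.append(
                MotifHit(
                    f[3], f[0], int(f[1]), int(f[2]), f[5],
                    score=np.nan, score_fraction=int(f[4]) / 1000.0,
                )
            )
    return hits


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """BED6: name = motif, score = round(1000 x score_fraction), strand."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.strand)):
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif_name}\t"
                f"{round(1000 * h.score_fraction)}\t{h.strand}\n"
            )
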