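"""Readers and writers for the text formats the pipeline touches.

FASTA goes through Biopython; BED and the tabular outputs are plain
whitespace-delimited text.  All interval formats are 0-based half-open.
"""

from __future__ import annotations

from typing import Iterable

from Bio import SeqIO

from .regions import GenomicRegion

__all__ = ["read_fasta", "write_fasta", "read_bed", "write_bed"]


def read_fasta(path) -> dict[str, str]:
    """Read FASTA records into ``{name: uppercased sequence}``.

    Duplicate record names and empty files are errors: downstream scanning
    addresses sequences by name and silently losing a record would corrupt
    hit coordinates.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: empty FASTA file")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path, region: GenomicRegion | None = None) -> list[GenomicRegion]:
    """Read BED3+ intervals, sorted by (chrom, start), optionally clipped to
    ``region`` (intervals outside it are dropped)."""
    out: list[GenomicRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            if e <= s:
                raise ValueError(f"{path}:{ln}: interval end {e} <= start {s}")
            iv = GenomicRegion(chrom, s, e)
            if region is not None:
                clipped = iv.intersect(region)
                if clipped is None:
                    continue
                iv = clipped
            out.append(iv)
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def write_bed(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
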