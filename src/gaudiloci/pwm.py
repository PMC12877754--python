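"""Position weight matrices: the MEME minimal and JASPAR PFM text formats.

A :class:`PWM` holds per-position probabilities over A, C, G, T.  JASPAR count
matrices are converted with a per-cell pseudocount, ``(c + p) / (sum(c) + 4p)``;
MEME probability rows are validated to sum to ~1 and then regularized with the
same pseudocount so every entry is strictly positive and log-odds stay finite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PWM", "read_pwms", "write_meme"]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PWM:
    """A TF binding motif as per-position base probabilities.

    ``matrix`` has shape (length, 4) in A, C, G, T order; each row sums to 1.
    ``background`` is the base composition used for log-odds scoring.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: matrix must be (length, 4)")
        if np.any(m <= 0):
            raise ValueError(f"motif {self.name!r}: zero/negative probability entry")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError(f"motif {self.name!r}: rows must sum to 1")
        if abs(bg.sum() - 1.0) > 1e-6 or np.any(bg <= 0):
            raise ValueError(f"motif {self.name!r}: invalid background")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background), shape (length, 4)."""
        return np.log2(self.matrix / self.background)

    def max_score(self) -> float:
        """Maximum attainable log-odds score over any sequence window."""
        return float(self.log_odds().max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.name, self.matrix[::-1, ::-1].copy(), self.background, self.pseudocount
        )

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=np.float64)
        if np.any(counts < 0):
            raise ValueError(f"motif {name!r}: negative count")
        probs = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )
        bg = np.full(4, 0.25) if background is None else background
        return cls(name, probs, bg, pseudocount)

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, match_prob: float = 0.97
    ) -> "PWM":
        """Near-deterministic PWM for a consensus string (testing/simulation)."""
        consensus = consensus.upper()
        m = np.full((len(consensus), 4), (1.0 - match_prob) / 3.0)
        for k, b in enumerate(consensus):
            if b not in _BASE_INDEX:
                raise ValueError(f"invalid consensus base {b!r}")
            m[k, _BASE_INDEX[b]] = match_prob
        return cls(name, m)

    @classmethod
    def from_probabilities(
        cls,
        name: str,
        probs: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        probs = np.asarray(probs, dtype=np.float64)
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-3:
            raise ValueError(f"motif {name!r}: probability rows must sum to ~1")
        if np.any(probs <= 0):  # regularize only when zeros would break log-odds
            reg = (probs + pseudocount) / (1.0 + 4 * pseudocount)
        else:
            reg = probs.copy()
        reg /= reg.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(name, reg, bg, pseudocount)


def read_pwms(path, fmt: str = "meme", pseudocount: float = 0.01) -> list[PWM]:
    """Read motifs from MEME minimal (``fmt='meme'``) or JASPAR PFM
    (``fmt='jaspar'``) text, preserving file order and names verbatim."""
    if fmt == "meme":
        return _read_meme(path, pseudocount)
    if fmt == "jaspar":
        return _read_jaspar(path, pseudocount)
    raise ValueError(f"unknown PWM format {fmt!r}")


def _read_meme(path, pseudocount: float) -> list[PWM]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = dict(zip(tokens[0::2], map(float, tokens[1::2])))
            background = np.array([freqs.get(b, 0.25) for b in BASES])
            background /= background.sum()
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().lower().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"{path}: motif {name!r} lacks a probability matrix")
            m = re.search(r"w=\s*(\d+)", lines[i])
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or not re.match(r"^[\d.eE+\-\s]+$", stripped):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            if m is not None and len(rows) != int(m.group(1)):
                raise ValueError(
                    f"{path}: motif {name!r} declares w={m.group(1)} "
                    f"but has {len(rows)} rows"
                )
            probs = np.asarray(rows)
            if probs.ndim != 2 or probs.shape[1] != 4:
                raise ValueError(f"{path}: motif {name!r}: rows must have 4 columns")
            motifs.append(
                PWM.from_probabilities(name, probs, pseudocount, background.copy())
            )
            continue
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return motifs


def _read_jaspar(path, pseudocount: float) -> list[PWM]:
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip()]
    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {lines[i]!r}")
        name = lines[i][1:].split()[0]
        rows = {}
        i += 1
        while i < len(lines) and not lines[i].startswith(">"):
            m = re.match(r"^\s*([ACGT])?\s*\[?\s*([\d.\s]+?)\s*\]?\s*$", lines[i])
            if m is None:
                raise ValueError(f"{path}: malformed JASPAR row {lines[i]!r}")
            base = m.group(1) if m.group(1) else BASES[len(rows)]
            rows[base] = [float(x) for x in m.group(2).split()]
            i += 1
        if set(rows) != set(BASES):
            raise ValueError(f"{path}: motif {name!r} lacks rows for all of ACGT")
        counts = np.array([rows[b] for b in BASES]).T  # (length, 4)
        motifs.append(PWM.from_counts(name, counts, pseudocount))
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_meme(pwms: list[PWM], path) -> None:
    """Write motifs in MEME minimal format (uniform background header)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
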