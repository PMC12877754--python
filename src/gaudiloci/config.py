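"""Pipeline-wide parameters with the published defaults.

The numeric defaults mirror the analysis procedure: 5 kb Hi-C bins over a
1 Mb window, top 20% of balanced interactions kept for the layout graph, a
buffer disc of 1.5x the mean interbin distance per bin, a TSS neighborhood of
3.0x the mean interbin distance, and retention of the bases carrying the top
10% of contribution scores.  The remaining fields (dummy ring, disc polygon
resolution, PWM score fraction) are geometry/scanning plumbing documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class PipelineConfig:
    resolution: int = 5000          # Hi-C bin width, bp
    top_fraction: float = 0.20      # fraction of nonzero interactions kept
    buffer_factor: float = 1.5      # buffer disc radius, x mean interbin distance
    neighborhood_factor: float = 3.0  # TSS neighborhood radius, x mean interbin distance
    contribution_quantile: float = 0.90  # per-base retention threshold quantile
    pwm_score_fraction: float = 0.8  # hit threshold as fraction of max log-odds
    dummy_count: int = 36           # Voronoi closing points on the outer ring
    dummy_radius_factor: float = 4.0  # ring radius, x layout centroid radius
    disc_segments: int = 64         # regular polygon sides approximating a disc
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.buffer_factor <= 0:
            raise ValueError(f"buffer_factor must be > 0, got {self.buffer_factor}")
        if self.neighborhood_factor <= 0:
            raise ValueError(
                f"neighborhood_factor must be > 0, got {self.neighborhood_factor}"
            )
        if not 0 < self.contribution_quantile < 1:
            raise ValueError(
                f"contribution_quantile must be in (0, 1), got {self.contribution_quantile}"
            )
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if not 0 < self.pwm_score_fraction <= 1:
            raise ValueError(
                f"pwm_score_fraction must be in (0, 1], got {self.pwm_score_fraction}"
            )
        if self.dummy_count < 3:
            raise ValueError("dummy_count must be >= 3 to close the plane")
        if self.disc_segments < 8:
            raise ValueError("disc_segments must be >= 8")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        typed = {}
        for k, v in d.items():
            target = cls.__dataclass_fields__[k].type
            if isinstance(v, str):
                v = int(v) if target == "int" else float(v)
            typed[k] = v
        return cls(**typed)
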