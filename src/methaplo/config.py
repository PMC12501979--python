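"""Run configuration shared across the pipeline stages.

All defaults are the analysis parameters used throughout the package:
200/100 bp sliding windows, a >5-cytosine window filter, context-specific
DMR thresholds of 25/25/15 percentage points at Q < 0.05, a minimum read
depth of 5 for site calling, and 2 kb flanks split into 20 bins around a
40-bin gene body for metaplots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class RunConfig:
    window_size: int = 200
    step_size: int = 100
    #: windows must contain strictly more than this many covered cytosines
    min_cytosines_per_window: int = 5
    dmr_diff_thresholds: dict = field(
        default_factory=lambda: {"CG": 25.0, "CHG": 25.0, "CHH": 15.0}
    )
    q_threshold: float = 0.05
    depth_min: int = 5
    flank_size: int = 2000
    body_bins: int = 40
    flank_bins: int = 20
    #: upstream span treated as the promoter in feature annotation
    promoter_size: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "window_size",
            "step_size",
            "min_cytosines_per_window",
            "depth_min",
            "flank_size",
            "body_bins",
            "flank_bins",
            "promoter_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if self.window_size < self.step_size:
            raise ValueError("window_size must be >= step_size")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        missing = set(CONTEXTS) - set(self.dmr_diff_thresholds)
        if missing:
            raise ValueError(f"dmr_diff_thresholds missing contexts: {sorted(missing)}")
        if any(v <= 0 for v in self.dmr_diff_thresholds.values()):
            raise ValueError("dmr_diff_thresholds must be positive")

    # -- persistence ---------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
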