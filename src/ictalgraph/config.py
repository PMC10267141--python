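"""Analysis configuration: frequency bands, segmentation and grids."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["Band", "BandSet", "DEFAULT_BANDS", "AnalysisConfig"]


@dataclass(frozen=True)
class Band:
    name: str
    low: float   # Hz
    high: float  # Hz

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: require 0 < low < high")


@dataclass(frozen=True)
class BandSet:
    bands: tuple[Band, ...]

    def __iter__(self):
        return iter(self.bands)

    def __len__(self):
        return len(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


#: The six physiologically relevant bands used throughout the analysis.
DEFAULT_BANDS = BandSet(
    (
        Band("delta", 2, 4),
        Band("theta", 5, 7),
        Band("alpha", 8, 12),
        Band("beta", 15, 29),
        Band("low_gamma", 30, 59),
        Band("high_gamma", 60, 90),
    )
)


@dataclass
class AnalysisConfig:
    """Pipeline parameters.

    segment_length_s x n_segments must equal the 60-s epoch duration; the
    node-epileptogenicity threshold grid spans [0, 1] in steps of 0.1 and the
    resection-overlap grid spans [0, 100]% in steps of 5%.
    """

    segment_length_s: float = 3.0
    n_segments: int = 20
    node_threshold_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    )
    overlap_grid_percent: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 100.0 + 1e-9, 5.0), 10)
    )
    alpha_level: float = 0.05
    rng_seed: int = 0
    # filter settings
    broadband: tuple[float, float] = (1.0, 100.0)
    notch_hz: float = 60.0
    notch_q: float = 30.0
    filter_order: int = 4
    edge_trim_fraction: float = 0.1  # analytic-signal edge trim per segment end
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        self.node_threshold_grid = np.asarray(self.node_threshold_grid, float)
        self.overlap_grid_percent = np.asarray(self.overlap_grid_percent, float)
        for name, grid in (
            ("node_threshold_grid", self.node_threshold_grid),
            ("overlap_grid_percent", self.overlap_grid_percent),
        ):
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if abs(self.n_segments * self.segment_length_s - 60.0) > 1e-9:
            raise ValueError(
                "n_segments * segment_length_s must equal the 60-s epoch duration"
            )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["node_threshold_grid"] = [float(x) for x in self.node_threshold_grid]
        d["overlap_grid_percent"] = [float(x) for x in self.overlap_grid_percent]
        d["bands"] = [[b.name, b.low, b.high] for b in self.bands]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "bands" in d:
            d["bands"] = BandSet(tuple(Band(n, lo, hi) for n, lo, hi in d["bands"]))
        if "broadband" in d:
            d["broadband"] = tuple(d["broadband"])
        return cls(**d)
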