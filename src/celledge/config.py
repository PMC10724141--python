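"""Pipeline configuration: one YAML/JSON file holding every tunable parameter.

Defaults encode the standard measurement regime for this kind of TIRF
morphodynamics analysis: 0.26 um/pixel, 40 s frame interval, a 3 um inward
measurement band, 100 circumference positions, +/-0.075 um/min
protrusion/retraction thresholds, and a 5-pixel peripheral band.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # inputs (ignored when `simulate` is true)
    movie_path: str | None = None
    volume_channel: str = "volume"
    signal_channel: str = "sensor"
    channel_order: list[str] = field(default_factory=lambda: ["volume", "sensor"])

    # calibration
    pixel_size: float = 0.26          # um / pixel
    frame_interval: float = 40.0      # s

    # edge mapping
    band_depth: float = 3.0           # um, inward signal band
    n_positions: int = 100
    min_area: int = 100               # px, segmentation size filter
    segmentation_method: str = "otsu"
    fixed_threshold: float | None = None

    # morphodynamics
    v_protrusion: float = 0.075       # um/min
    v_retraction: float = -0.075      # um/min
    shift_range_s: float = 400.0      # enrichment shifts span +/- this
    max_lag_s: float = 400.0          # cross-correlation lag range
    smoothing_window: int = 0         # frames; 0 = no velocity smoothing

    # central/peripheral split
    peripheral_band_pixels: int = 5

    # kinetics
    baseline_frames: tuple[int, int] = (0, 5)
    background_dilation: int = 10

    # migration
    max_link_distance: float = 20.0   # um
    observation_frames: int = 240     # cohort window at 1 frame/min

    # synthetic-movie source (used by `simulate` and when movie_path is None)
    simulate: bool = False
    synthetic: dict = field(default_factory=dict)

    seed: int = 0

    def validate(self) -> None:
        for name in ("pixel_size", "frame_interval", "band_depth",
                     "shift_range_s", "max_lag_s", "max_link_distance"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"config field {name} must be > 0")
        if self.n_positions < 8:
            raise ParameterError("config field n_positions must be >= 8")
        if not self.v_retraction < self.v_protrusion:
            raise ParameterError(
                "config fields v_retraction/v_protrusion are out of order"
            )
        if self.peripheral_band_pixels < 1:
            raise ParameterError("config field peripheral_band_pixels must be >= 1")
        lo, hi = self.baseline_frames
        if hi <= lo or lo < 0:
            raise ParameterError("config field baseline_frames must be a valid range")
        if self.smoothing_window < 0:
            raise ParameterError("config field smoothing_window must be >= 0")
        if not self.simulate and self.movie_path is None:
            raise ParameterError("config field movie_path is required unless simulate")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        if "baseline_frames" in data:
            data["baseline_frames"] = tuple(data["baseline_frames"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_frames"] = list(d["baseline_frames"])
        return d

    def content_hash(self) -> str:
        """Stable hash of the configuration for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
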