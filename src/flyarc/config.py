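"""Run configuration: defaults, YAML round-trip, and config hashing.

All analysis defaults equal the assay's standard values (4.0 s.d. noise
filtration, 3.5 s.d. meal selection, >300 s sleep, 0.5 FBL motion
filter, 0.01 ul/px calibration, 60-min alignment window, 0.01 ul volume
bins); every override is visible in the config hash stamped on outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    # calibration and thresholds
    volume_per_px: float = 0.01          # ul per pixel of band travel
    noise_sd_multiplier: float = 4.0     # iterative filtration cut
    meal_sd_multiplier: float = 3.5      # meal selection cut
    min_sleep_s: int = 300               # immobility > 5 min is sleep
    fbl_fraction: float = 0.5            # motion filter, fraction of FBL
    # image processing
    rolling_ball_radius: int = 5
    binarize_threshold: float = 60.0
    min_feature_area_px: int = 4
    # alignment / grading
    align_window_min: int = 60
    dpsleep_span_min: int = 20
    volume_bin_ul: float = 0.01
    volume_percentile_cut: float = 97.0
    nutrient_volume_window_ul: tuple[float, float] = (0.02, 0.04)
    # diet (% w/v per component)
    diet: dict[str, float] = field(
        default_factory=lambda: {"sucrose": 2.5, "yeast_extract": 2.5}
    )
    # masking epochs: daily food change ZT 0-0.5 h
    zt0_offset_s: int = 0
    mask_food_change: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_per_px <= 0:
            raise ParameterError("volume_per_px must be > 0")
        if self.noise_sd_multiplier <= 0 or self.meal_sd_multiplier <= 0:
            raise ParameterError("s.d. multipliers must be > 0")
        if self.min_sleep_s <= 0:
            raise ParameterError("min_sleep_s must be > 0")
        if not 0 < self.fbl_fraction < 1:
            raise ParameterError("fbl_fraction must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["nutrient_volume_window_ul"] = list(d["nutrient_volume_window_ul"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "nutrient_volume_window_ul" in raw:
            raw["nutrient_volume_window_ul"] = tuple(raw["nutrient_volume_window_ul"])
        return cls(**raw)

    def hash(self) -> str:
        """Short stable digest of the full config, stamped on outputs."""
        canon = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha1(canon.encode()).hexdigest()[:12]
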