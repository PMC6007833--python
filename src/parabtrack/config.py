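"""Pipeline-wide configuration.

A single :class:`PipelineConfig` carries every tunable constant of the
analysis — pixel geometry, smoothing width, peak-detection and validation
settings, track-linking radii, the MSD distance bins and the velocity
threshold — so that one YAML/JSON file plus one seed fully determines a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All analysis parameters with their defaults.

    Units are encoded in the field names: ``_um`` micrometres, ``_px``
    pixels, ``_h`` hours.
    """

    pixel_size_um: float = 0.1
    frame_interval_h: float = 0.25
    smoothing_sigma_px: float = 2.0
    peak_min_separation_px: int = 5
    peak_threshold_rel: float = 0.3
    noise_trials: int = 20
    noise_retain_min: int = 10
    noise_sigma_factor: float = 0.5
    resmooth_sigma_px: float = 2.0
    match_radius_px: float = 2.0
    link_max_px: float = 5.0
    split_radius_px: float = 10.0
    velocity_threshold_um_h: float = 0.15
    msd_bin_edges_um: list[float] = field(default_factory=lambda: [0.0, 1.5, 3.0, 4.5])
    minicell_max_um: float = 2.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if self.smoothing_sigma_px <= 0:
            raise ValueError("smoothing_sigma_px must be positive")
        if self.peak_min_separation_px < 1:
            raise ValueError("peak_min_separation_px must be >= 1")
        if not (0 < self.noise_retain_min <= self.noise_trials):
            raise ValueError("need 0 < noise_retain_min <= noise_trials")
        if self.link_max_px <= 0 or self.split_radius_px <= 0:
            raise ValueError("linking radii must be positive")
        if self.velocity_threshold_um_h < 0:
            raise ValueError("velocity_threshold_um_h must be >= 0")
        edges = list(self.msd_bin_edges_um)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("msd_bin_edges_um must be strictly increasing, >= 2 edges")
        self.msd_bin_edges_um = [float(e) for e in edges]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash identifying this parameter set (seed excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "seed"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
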