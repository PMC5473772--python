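"""Run configuration: one YAML-serialisable object holding every knob.

Defaults follow the published analysis conventions wherever one exists:
signal fraction 0.10, background fraction 0.50, intensity cutoff 65,000,
ratio cutoff 5, area window 10 px, minimum 10 cells per bin, regression axis
caps 65,000 (x) and 15,000 (y).  The configuration round-trips through YAML
losslessly, so a written config re-read and re-run reproduces a pipeline
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binding import OccupancyParams
from .quantify import QuantConfig
from .simulate import OpticsNoiseConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All parameters of a simulate -> quantify -> analyze pipeline run."""

    seed: int = 0
    n_cells: int = 300
    cells_per_field: int = 60
    frame_shape: tuple[int, int] = (512, 512)
    full_length_pool: float = 300.0
    split_pool: float = 2000.0
    sites_per_array: int = 64
    affinity: float = 10.0
    free_complementation_rate: float = 0.002
    quant: QuantConfig = field(default_factory=QuantConfig)
    optics: OpticsNoiseConfig = field(default_factory=OpticsNoiseConfig)
    bin_window: float = 10.0
    bin_min_cells: int = 10
    bin_mode: str = "disjoint"
    regression_x_cap: float = 65000.0
    regression_y_cap: float = 15000.0
    fold_subset_fraction: float = 1.0

    def occupancy(self, construct: str, n_arrays: int) -> OccupancyParams:
        pool = {
            "full_length": self.full_length_pool,
            "split": self.split_pool,
            "empty": 0.0,
        }[construct]
        return OccupancyParams(
            pool_size=pool,
            n_arrays=n_arrays,
            sites_per_array=self.sites_per_array,
            affinity=self.affinity,
            free_complementation_rate=self.free_complementation_rate,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["quant"]["histogram_bins"] = [float(b) for b in self.quant.histogram_bins]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "quant" in data and isinstance(data["quant"], dict):
            q = dict(data["quant"])
            if "histogram_bins" in q:
                q["histogram_bins"] = tuple(q["histogram_bins"])
            data["quant"] = QuantConfig(**q)
        if "optics" in data and isinstance(data["optics"], dict):
            data["optics"] = OpticsNoiseConfig(**data["optics"])
        if "frame_shape" in data:
            data["frame_shape"] = tuple(data["frame_shape"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
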