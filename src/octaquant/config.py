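"""Flat key:value pipeline configuration.

One dataclass gathers every stage parameter; it round-trips unchanged
through a plain ``key = value`` text file so a run can be reproduced from
its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    # quality control
    min_ssi: float = 8.0
    # binarization
    despeckle_px: int = 3
    tophat_radius_px: int = 12
    hessian_sigma_px: float = 1.2
    tubeness_floor: float = 0.02
    median_radius_px: int = 15
    median_offset: float = 0.06
    min_object_px: int = 20
    fill_holes_px: int = 0
    # geometry
    pixel_pitch_um: float = 12.0
    faz_diameter_mm: float = 0.6
    parafoveal_diameter_mm: float = 2.5
    perifoveal_diameter_mm: float = 5.5
    auto_center: bool = False  # locate the fovea instead of using mid-raster
    # metrics
    vt_min_branch_px: float = 3.0
    vt_prune_px: float = 12.0  # end-twig pruning before branch analysis
    vdi_as_pixels: bool = False
    # cohort simulation / statistics
    n_per_group: int = 24
    within_eye_corr: float = 0.5
    interobserver_corr: float = 0.995
    bonferroni_m: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_ssi <= 10:
            raise ConfigError("min_ssi must lie in [0, 10]")
        if self.tophat_radius_px < 1 or self.median_radius_px < 1:
            raise ConfigError("filter radii must be >= 1 px")
        if self.hessian_sigma_px <= 0:
            raise ConfigError("hessian sigma must be positive")
        if not self.faz_diameter_mm < self.parafoveal_diameter_mm \
                < self.perifoveal_diameter_mm:
            raise ConfigError("region diameters must be strictly increasing")

    # -- serialization ----------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ConfigError(f"line {lineno}: unknown parameter '{key}'")
            t = types[key]
            if t in ("bool", bool):
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif t in ("int", int):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
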