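"""Pipeline configuration: acquisition geometry, stage parameters, seeds.

Defaults follow the reference acquisition where one is printed —
1.74 µm isotropic voxels, 500 projections over 180° — and the package's
own documented choices elsewhere.  All randomness flows from the single
``seed``, fanned out with fixed offsets per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .segmentation import CannyParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    voxel_size_um: float = 1.74
    n_projections: int = 500
    angular_range_deg: float = 180.0
    edge_strength: float = 0.3
    photons_per_pixel: float = 1.0e6
    attenuation_per_unit: float = 0.002
    canny: CannyParams = field(default_factory=CannyParams)
    segmentation_axes: tuple[int, ...] = (0,)
    filter_kind: str = "ramp"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.canny, dict):
            self.canny = CannyParams(**self.canny)
        self.segmentation_axes = tuple(self.segmentation_axes)
        if not (self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be positive")
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if not (0 < self.angular_range_deg <= 180):
            raise ValueError("angular_range_deg must lie in (0, 180]")

    # stage-specific seeds derived from the master seed (kept below 2**31)
    @property
    def phantom_seed(self) -> int:
        return (self.seed * 9973 + 1) % (2**31)

    @property
    def noise_seed(self) -> int:
        return (self.seed * 9973 + 2) % (2**31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation_axes"] = list(self.segmentation_axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
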