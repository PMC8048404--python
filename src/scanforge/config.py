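"""Project configuration: the YAML description of one scan project.

Mirrors the scanner's project-configuration file: input/output locations,
the angle grid of the two gimbal axes, the focus-filter threshold, masking
parameters, camera intrinsics, cut-out mode and grey projector.  Configs
round-trip losslessly through YAML so presets can be saved and reloaded.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .mask import MaskParams
from .poses import CameraIntrinsics


@dataclass
class AxisRange:
    """min/max/step (degrees) of one gimbal axis, inclusive of both ends."""

    min_deg: float
    max_deg: float
    step_deg: float

    def angles(self) -> list[float]:
        if self.step_deg <= 0:
            raise ConfigurationError("axis step must be positive")
        n = int(round((self.max_deg - self.min_deg) / self.step_deg)) + 1
        return [self.min_deg + i * self.step_deg for i in range(max(n, 1))]


@dataclass
class ProjectConfig:
    input_dir: str = "."
    output_dir: str = "out"
    x_axis: AxisRange = field(default_factory=lambda: AxisRange(-50.0, 50.0, 20.0))
    y_axis: AxisRange = field(default_factory=lambda: AxisRange(0.0, 342.0, 18.0))
    radius_mm: float = 220.0
    focus_threshold: float = 0.0
    mask_params: MaskParams = field(default_factory=MaskParams)
    intrinsics: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    cutout_mode: str = "zero"
    grey_projector: str = "average"
    blend_window: int = 7

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ProjectConfig":
        try:
            kwargs = dict(raw)
            for key, sub in (("x_axis", AxisRange), ("y_axis", AxisRange),
                             ("mask_params", MaskParams),
                             ("intrinsics", CameraIntrinsics)):
                if key in kwargs and isinstance(kwargs[key], dict):
                    kwargs[key] = sub(**kwargs[key])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad project config: {exc}") from exc
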