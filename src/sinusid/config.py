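"""Study configuration: one YAML/JSON file drives a full replication run.

Every run copies its resolved configuration next to its outputs, so any
table can be traced back to the exact generator, registration and threshold
settings that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .protocols import ICPParams
from .stats import DEFAULT_THRESHOLD_MM
from .synthetic import NoiseModel

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """All knobs of one replication run.

    n_subjects : subjects per sample (50 matches + 50 mismatches at 50).
    master_seed : seeds the whole cohort (shapes, noise, pairing).
    voxel_pitch : marching-cubes resolution in mm; the fidelity/speed knob.
    threshold_mm : RMS identification threshold.
    """

    n_subjects: int = 50
    master_seed: int = 42
    voxel_pitch: float = 1.0
    threshold_mm: float = DEFAULT_THRESHOLD_MM
    output_dir: str = "study_out"
    noise: NoiseModel = field(default_factory=NoiseModel)
    icp: ICPParams = field(default_factory=lambda: ICPParams(sample_size=2000, tolerance_mm=3e-3))

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.voxel_pitch <= 0 or self.threshold_mm <= 0:
            raise ValueError("voxel_pitch and threshold_mm must be positive")
        if self.icp.max_iterations < 1 or self.icp.tolerance_mm <= 0:
            raise ValueError("invalid ICP parameters")

    @classmethod
    def quick(cls, **overrides) -> "StudyConfig":
        """Small fast profile (10 subjects, coarser meshes) for smoke runs."""
        defaults = dict(n_subjects=10, voxel_pitch=1.5)
        defaults.update(overrides)
        return cls(**defaults)

    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        noise = NoiseModel(**data.pop("noise", {}))
        icp = ICPParams(**data.pop("icp", {}))
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(noise=noise, icp=icp, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a configuration mapping")
        return cls.from_dict(data)
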