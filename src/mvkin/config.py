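"""Pipeline configuration: one TOML (or YAML) file drives every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class TriangulationConfig:
    min_confidence: float = 0.3
    max_reproj_error: float = 15.0
    max_gap: int = 5

    def __post_init__(self):
        if not 0 <= self.min_confidence < 1:
            raise ValueError("min_confidence must lie in [0, 1)")
        if self.max_reproj_error < 0 or self.max_gap < 0:
            raise ValueError("max_reproj_error and max_gap must be >= 0")


@dataclass
class FilterConfig:
    order: int = 4
    cutoff: float = 6.0
    zero_phase: bool = True


@dataclass
class EventsConfig:
    task: str = "walking"
    cadence: float = 1.0
    progression_axis: int = 0
    vertical_axis: int = 1


@dataclass
class IkConfig:
    max_iterations: int = 200
    tol: float = 1e-8
    keypoint_offsets: dict = field(default_factory=dict)


@dataclass
class AgreementConfig:
    normalized_length: int = 101
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    pose_dir: str = ""
    rig_file: str = ""
    model_file: str = ""  # empty -> shipped default model
    static_pose_dir: str = ""  # static-trial detections for scaling
    reference_trc: str = ""  # marker-based channel (optional)
    output_dir: str = "output"
    seed: int = 0
    triangulation: TriangulationConfig = field(default_factory=TriangulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    events: EventsConfig = field(default_factory=EventsConfig)
    ik: IkConfig = field(default_factory=IkConfig)
    agreement: AgreementConfig = field(default_factory=AgreementConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("triangulation", TriangulationConfig),
            ("filter", FilterConfig),
            ("events", EventsConfig),
            ("ik", IkConfig),
            ("agreement", AgreementConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from TOML (or YAML, by extension)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        from mvkin.io import load_toml

        data = load_toml(path)
    return PipelineConfig.from_dict(data)
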