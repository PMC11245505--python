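"""Pipeline configuration: one dataclass, YAML round-trip, content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, with explicit per-stage seeds.

    Paths are interpreted relative to the invoker's working directory.
    ``seed`` feeds every stage whose own seed is left as ``None``.
    """

    # inputs
    masks_dir: str = "masks"
    manifest_csv: str = "eyes.csv"
    clinical_csv: str = "clinical.csv"
    outcomes_csv: str = "outcomes.csv"
    out_dir: str = "runs"
    # quantification policy
    abscess_mode: str = "depth"  # depth | area
    occlusion_target: str = "pupil"  # pupil | cornea
    pupil_policy: str = "strict"  # strict | clip
    fusion_rule: str = "max"  # max | mean
    # modeling
    tasks: tuple[str, ...] = ("perforation_1m", "perforation_3m", "vision_1m", "vision_3m")
    algorithm: str = "xgb"  # xgb | lgbm
    split_ratio: float = 0.8
    cv_folds: int = 5
    threshold: float = 0.5
    bootstrap_replicates: int = 2000
    boost_params: dict = field(default_factory=dict)
    # seeds
    seed: int = 0
    split_seed: int | None = None
    screen_seed: int | None = None
    model_seed: int | None = None
    bootstrap_seed: int | None = None
    # reporting
    round_digits: int = 2

    def stage_seed(self, name: str) -> int:
        value = getattr(self, f"{name}_seed")
        return int(self.seed if value is None else value)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tasks"] = list(d["tasks"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
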