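"""Pipeline configuration: one structured file drives a reproducible run."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """All thresholds, paths and the master seed of one pipeline run.

    Threshold defaults: R² minimum 0.80 (strictly-below excluded), fold
    change 1.30 up / 0.70 down (boundary inclusive), 2000 resampling
    iterations, mapping rank cutoff 4, at least 3 substrates per scored
    kinase, volcano cutoffs log2(1.30) on fold change and 1.3 on the final
    score.
    """

    signals: str = ""
    map_file: str = ""
    family_file: str | None = None
    out_dir: str = "out"
    case_group: str = "treatment"
    control_group: str = "control"
    r2_min: float = 0.80
    detect_min: float = 2.0
    saturation_ceiling: float = 65535.0
    floor: float = 1.0
    fc_up: float = 1.30
    fc_down: float = 0.70
    n_iterations: int = 2000
    rank_max: int = 4
    min_substrates: int = 3
    score_cut: float = 1.3
    lfc_cut: float = field(default_factory=lambda: math.log2(1.30))
    top_k: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValidationError(
                f"need fc_down < 1 < fc_up, got ({self.fc_down}, {self.fc_up})"
            )
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValidationError("r2_min must be in [0, 1]")


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys raise, missing keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration (provenance stamp)."""
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
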