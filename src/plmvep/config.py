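"""Run configuration with the published default constants."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .errors import ValidationError
from .isoforms import SensitivityThresholds
from .tiling import EdgeWeightParams


@dataclass
class RunConfig:
    """All knobs in one place; defaults match the published constants."""

    backend_kind: str = "synthetic"
    backend_seed: int = 0
    max_input_length: int = 1022

    window_length: int = 1022
    min_overlap: int = 511
    aggregation_mode: str = "weighted"
    sigmoid_steepness: float = 0.1
    sigmoid_margin: int = 127

    benign_floor: float = -7.0
    pathogenic_ceiling: float = -8.0
    min_difference: float = 4.0
    high_variance_sd: float = 2.0
    classification_cutoff: float = -7.5

    prc_repeats: int = 100
    prc_frac: float = 0.8
    permutations: int = 2000
    bootstrap_n_pos: int = 140
    bootstrap_n_neg: int = 140
    bootstrap_iters: int = 20

    indel_mode: str = "vanilla"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.min_overlap >= self.window_length:
            raise ValidationError("min_overlap must be below window_length")

    def edge_weight_params(self) -> EdgeWeightParams:
        return EdgeWeightParams(
            steepness=self.sigmoid_steepness, margin=self.sigmoid_margin
        )

    def sensitivity_thresholds(self) -> SensitivityThresholds:
        return SensitivityThresholds(
            benign_floor=self.benign_floor,
            pathogenic_ceiling=self.pathogenic_ceiling,
            min_difference=self.min_difference,
            high_variance_sd=self.high_variance_sd,
            classification_cutoff=self.classification_cutoff,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
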