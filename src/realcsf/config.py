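"""Pipeline configuration: every tunable constant in one place, loadable
from a YAML (or key: value) file.  CLI flags override file values."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml


@dataclass
class PipelineConfig:
    interval_width: int = 500_000
    focal_flank: int = 1_000_000
    k_components: int = 5
    min_panel_size: int = 10
    cbs_alpha: float = 0.01
    cbs_min_width: int = 3
    cbs_n_perm: int = 1000
    outlier_mad_mult: float = 4.0
    germline_max_intervals: int = 6
    germline_z: float = 4.0
    min_retained: int = 10
    gain_threshold: float = 7.5
    loss_threshold: float = -7.5
    gas_threshold: float = 0.25
    focal_threshold: float = 7.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
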