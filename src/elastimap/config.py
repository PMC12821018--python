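"""Run configuration for the batch entry points.

All analysis defaults live here so that the CLI, the library and any
config file agree on them: the 10% setpoint-deviation QC tolerance, the
pre-contact baseline fraction, the one-hour postmortem binning starting
at 1.5 h, the 38 degC reference temperature for relative slopes and the
0.05 significance level. A :class:`RunConfig` round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    model: str = "hertz"               # contact model used for fitting
    qc_tolerance: float = 0.10         # relative setpoint-deviation limit
    baseline_fraction: float = 0.5     # leading fraction of z span for baseline
    stiffness_window: tuple[float, float] = (0.90, 1.00)
    bin_start_h: float = 1.5           # first postmortem bin edge
    bin_width_h: float = 1.0
    T_ref: float = 38.0                # reference for relative slope (%/degC)
    alpha: float = 0.05                # F-test significance level
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.model not in ("hertz", "sneddon"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.qc_tolerance < 1:
            raise ValueError("qc_tolerance must be in (0, 1)")
        if not 0 < self.baseline_fraction <= 0.9:
            raise ValueError("baseline_fraction must be in (0, 0.9]")
        self.stiffness_window = tuple(self.stiffness_window)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["stiffness_window"] = list(self.stiffness_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)
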