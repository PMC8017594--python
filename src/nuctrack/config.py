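"""Run configuration: paper-derived constants with TOML/flag overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the pipeline.

    Defaults are the calibrated study constants: a 0.12 um nuclear
    displacement noise floor (pooled median of sessile cells), the 0-40 /
    140-180 degree angle blocks, and the 0.05 um/min sessile speed cutoff.
    """

    tau_um: float = 0.12
    low_block_max_deg: float = 40.0
    high_block_min_deg: float = 140.0
    sessile_speed_um_min: float = 0.05
    velocity_reference: str = "NC"  # {CC, NC}
    footprint_weighting: str = "duration"  # {duration, uniform}
    distal_k: float = 1.0  # equivalent-radius multiple for distal centrosomes
    asym_f: float = 0.25  # cell-radius fraction for asymmetric metaphases
    frame_interval_min: float = 5.0
    pixel_size_um: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.tau_um < 0:
            raise ValueError("tau_um must be >= 0")
        if not 0 < self.low_block_max_deg < self.high_block_min_deg < 180:
            raise ValueError(
                "need 0 < low_block_max_deg < high_block_min_deg < 180"
            )
        if self.velocity_reference.upper() not in ("CC", "NC"):
            raise ValueError("velocity_reference must be CC or NC")
        if self.footprint_weighting not in ("duration", "uniform"):
            raise ValueError("footprint_weighting must be duration or uniform")
        if self.sessile_speed_um_min <= 0 or self.frame_interval_min <= 0:
            raise ValueError("speed threshold and frame interval must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig: defaults < TOML file < explicit overrides."""
    values: dict = {}
    if path is not None:
        import tomllib

        with open(Path(path), "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("nuctrack", data)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        values.update(section)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
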