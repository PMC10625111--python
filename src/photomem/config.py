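"""Run configuration shared by the CLI pipeline.

Defaults mirror the experimental constants of the electrodeformation /
fluctuation-spectroscopy protocol: 296 K, eps_r,W = 80, crossover modes
starting at q = 3, AFM rejection thresholds 1 nm / 0.5 nm and a 10x10
smoothing window.  A flat ``key = value`` config file (TOML-style scalars
only) can override any field; CLI flags take precedence over the file.
Every analysis report embeds the configuration and package version used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .constants import DEFAULT_TEMPERATURE, WATER_RELATIVE_PERMITTIVITY


@dataclass
class RunConfig:
    temperature: float = DEFAULT_TEMPERATURE  # K
    eps_water: float = WATER_RELATIVE_PERMITTIVITY
    q_min: int = 3
    q_max: int = 0            # 0 -> auto (n_points/8)
    afm_reject_first_nm: float = 1.0
    afm_reject_second_nm: float = 0.5
    afm_smooth_window: int = 10
    afm_bin_width_nm: float = 0.05
    afm_min_separation_nm: float = 1.0
    seed: int = 0
    outdir: str = "out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key = value file; unknown keys raise."""
        cfg = cls()
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cfg, key)
            caster = type(current)
            value = value.strip("\"'")
            try:
                setattr(cfg, key, caster(value))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc
        return cfg

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
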