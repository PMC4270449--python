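"""Pipeline configuration.

Defaults mirror the acquisition and analysis parameters of the clinical
protocol the pipeline reproduces: 1024 Hz sampling, 2-s epochs (0.5 Hz
spectral resolution), 90 analyzed epochs, the four-band delta/theta/
pre-alpha/alpha scheme, and the posterior derivations Pz, P3, P4, O1, O2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .bands import BandScheme, DEFAULT_BANDS
from .descriptors import DFV_ESTIMATORS
from .recording import REGIONS


@dataclass
class PipelineConfig:
    epoch_length: float = 2.0
    n_epochs: int = 90
    fs: float = 1024.0
    region: str = "posterior"
    dfv_estimator: str = "range_width"
    artifact_limit_uv: float = 100.0
    seed: int = 0
    bands: BandScheme = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or self.n_epochs < 2:
            raise ValueError("epoch_length must be > 0 and n_epochs >= 2")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {sorted(REGIONS)}")
        if self.dfv_estimator not in DFV_ESTIMATORS:
            raise ValueError(f"dfv_estimator must be one of {DFV_ESTIMATORS}")
        if self.artifact_limit_uv <= 0:
            raise ValueError("artifact_limit_uv must be positive")

    @property
    def region_channels(self) -> tuple:
        return REGIONS[self.region]

    def echo(self) -> dict:
        """Effective configuration, embedded in every run report."""
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.edges.items()}
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load overrides from a flat key-value (YAML) file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        bands = data.pop("bands", None)
        cfg = cls(**data)
        if bands:
            cfg.bands = BandScheme(edges={k: tuple(v) for k, v in bands.items()})
        return cfg
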