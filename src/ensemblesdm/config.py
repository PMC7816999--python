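"""Run configuration: every numeric setting of the pipeline in one
round-trippable YAML-backed structure."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class GridConfig:
    origin_lon: float = 30.0
    origin_lat: float = 0.0
    cell_size: float = 0.1
    n_rows: int = 100
    n_cols: int = 100


@dataclass
class SyntheticConfig:
    """Virtual-world parameters; defaults give 6 partially collinear
    layers with 2 informative ones and 150 presences."""

    n_layers: int = 6
    smoothness: float = 8.0
    collinearity: float = 0.9
    n_gcm: int = 2
    shift: float = 1.0
    gcm_noise: float = 0.3
    optima: dict = field(default_factory=lambda: {"BIO3": 0.5, "BIO5": -0.3})
    widths: dict = field(default_factory=lambda: {"BIO3": 0.8, "BIO5": 0.8})
    n_presences: int = 150
    n_countries: int = 5
    pa_target_fraction: float = 0.3


@dataclass
class RunConfig:
    """All thresholds carry the pipeline's standard defaults: pairwise
    |r| <= 0.7, VIF <= 3, 1-degree calibration buffer, ten runs of
    four-fold cross-validation, stability quantiles 0.90/0.95/0.99."""

    seed: int = 1
    grid: GridConfig = field(default_factory=GridConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    r_max: float = 0.7
    vif_max: float = 3.0
    buffer_deg: float = 1.0
    folds: int = 4
    runs: int = 10
    stability_probs: tuple = (0.90, 0.95, 0.99)
    upscale_factor: int = 1
    sre_quantile: float = 0.025
    config_excluded: list = field(default_factory=list)
    loess_span: float = 0.5
    curve_points: int = 100

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.runs < 1:
            raise ValueError("runs must be at least 1")
        if not 0 < self.r_max <= 1:
            raise ValueError("r_max must be in (0, 1]")
        if self.vif_max <= 1:
            raise ValueError("vif_max must exceed 1")
        if self.buffer_deg <= 0:
            raise ValueError("buffer_deg must be positive")
        if self.upscale_factor < 1:
            raise ValueError("upscale_factor must be at least 1")
        if len(self.stability_probs) != 3 or list(self.stability_probs) != sorted(
            self.stability_probs
        ):
            raise ValueError("stability_probs must be 3 increasing probabilities")
        if not 0 <= self.sre_quantile < 0.5:
            raise ValueError("sre_quantile must be in [0, 0.5)")
        if set(self.synthetic.optima) != set(self.synthetic.widths):
            raise ValueError("optima and widths must name the same layers")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["stability_probs"] = list(self.stability_probs)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        grid = GridConfig(**doc.pop("grid", {}))
        synth = SyntheticConfig(**doc.pop("synthetic", {}))
        cfg = cls(grid=grid, synthetic=synth, **doc)
        cfg.stability_probs = tuple(cfg.stability_probs)
        cfg.validate()
        return cfg
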