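"""Pipeline configuration: every scalar setting in one validated structure.

Defaults reproduce the package's reference study conditions: a 40x40 grid
of 0.1 degree cells, 30 envelope-truth species, three future scenarios with
warming 3.1-4.4 degC, a ~7.2% clumped protected-area network, 50
calibration repetitions at 75/25, majority consensus at 0.5, and ABF
prioritization (z = 0.25) with vegetation weight 5 at a 17% coverage
target. Unknown keys are rejected so typos cannot silently change a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synth import ScenarioDelta


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class GridConfig:
    n_rows: int = 40
    n_cols: int = 40
    cell_size: float = 0.1
    origin: tuple[float, float] = (-55.0, -30.0)


@dataclass
class SpeciesConfig:
    n_species: int = 30
    breadth_log_mean: float = -0.597837000755620  # log(0.55)
    breadth_log_sd: float = 0.35
    iucn_mix: dict = field(default_factory=lambda: {
        "LC": 0.50, "NT": 0.10, "VU": 0.15, "DD": 0.05, "EN": 0.12, "CR": 0.08,
    })
    min_range_cells: int = 5


@dataclass
class LandscapeConfig:
    pa_fraction: float = 820 / 11461  # the reference network share
    veg_smooth_width: int = 7
    veg_logit_scale: float = 2.0


@dataclass
class ClimateConfig:
    noise_sd: float = 1.0
    scenarios: list = field(default_factory=lambda: [
        {"scenario_id": "gcm1_2080", "temp_offset": 3.1,
         "precip_multiplier": 0.95, "gradient_strength": 0.5},
        {"scenario_id": "gcm2_2080", "temp_offset": 3.75,
         "precip_multiplier": 0.92, "gradient_strength": 0.5},
        {"scenario_id": "gcm3_2080", "temp_offset": 4.4,
         "precip_multiplier": 0.90, "gradient_strength": 0.5},
    ])

    def deltas(self) -> list[ScenarioDelta]:
        return [ScenarioDelta(**d) for d in self.scenarios]


@dataclass
class EnmConfig:
    methods: list = field(default_factory=lambda: ["envelope", "logistic", "distance"])
    n_reps: int = 50
    calib_frac: float = 0.75
    envelope_pct: float = 95.0


@dataclass
class EnsembleConfig:
    consensus_threshold: float = 0.5
    anova_numerator: str = "main_effects"  # or "main_plus_interaction"


@dataclass
class DispersalConfig:
    alpha_coefficient: float = 2.0
    truncation_factor: float = 3.0
    combine: str = "geomean"  # geomean | min | product


@dataclass
class PrioritizerConfig:
    rule: str = "abf"  # abf | basic
    z: float = 0.25
    fraction: float = 0.17
    vegetation_weight: float = 5.0


@dataclass
class PipelineConfig:
    seed: int = 1
    grid: GridConfig = field(default_factory=GridConfig)
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    enm: EnmConfig = field(default_factory=EnmConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    dispersal: DispersalConfig = field(default_factory=DispersalConfig)
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "grid": GridConfig, "species": SpeciesConfig,
            "landscape": LandscapeConfig, "climate": ClimateConfig,
            "enm": EnmConfig, "ensemble": EnsembleConfig,
            "dispersal": DispersalConfig, "prioritizer": PrioritizerConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_dict(section_cls, data.pop(name) or {})
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ConfigError(f"unknown config keys: {sorted(data)}")
        cfg = cls(**kwargs)
        if isinstance(cfg.grid.origin, list):
            cfg.grid.origin = tuple(cfg.grid.origin)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"]["origin"] = list(d["grid"]["origin"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
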