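"""Run configuration: plain-text (YAML) config files and scale presets.

A run configuration bundles the settings of every pipeline stage:
``[environment]`` (scenario, years, seasonal phases), ``[founders]``
(family design, h2, CV), ``[herd]`` (every constant of the bioenergetic
model), ``[scheme]`` (breeding-nucleus structure), ``[goals]`` (index
weights) and ``[link]`` (re-simulation size and horizons), plus the master
seed and output directory.

Two scale presets are provided: ``paper`` (the full-scale study design:
200 x 100 founder families, a 20,000-cow nucleus, 30 replicates) and
``desk`` (a reduced design for interactive use: 50 x 40 founders, a
2,000-cow nucleus, 5 replicates).  Presets shrink counts only; model
constants are never touched by a preset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .breedsim import SchemeConfig
from .herd_model import HerdConfig


class ConfigError(ValueError):
    pass


PRESETS = ("paper", "desk")


@dataclass
class FounderDesign:
    n_sires: int = 200
    daughters_per_sire: int = 100
    h2: float = 0.35
    cv: float = 0.10


@dataclass
class LinkSettings:
    n_resim: int = 2000
    horizons: tuple = (10, 20, 30)
    scenarios: tuple = ("HS", "MS")
    use_estimated_panel: bool = False  # scheme runs on the packaged
    # reference panel by default; set True to use the step-1 estimates


@dataclass
class RunConfig:
    seed: int = 1
    preset: str = "paper"
    out_dir: str = "runs"
    scenario: str = "HS"
    n_years: int = 13
    offer_peak_day: float = 300.0
    me_peak_day: float = 100.0
    founders: FounderDesign = field(default_factory=FounderDesign)
    herd: HerdConfig = field(default_factory=HerdConfig)
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    link: LinkSettings = field(default_factory=LinkSettings)
    goals: list = field(default_factory=lambda: ["Base"])

    def apply_preset(self) -> "RunConfig":
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; "
                              f"expected one of {PRESETS}")
        if self.preset == "desk":
            self.founders = dataclasses.replace(
                self.founders, n_sires=50, daughters_per_sire=40)
            self.scheme = dataclasses.replace(
                self.scheme, n_cows=2000, n_herds=20, n_sires_per_year=10,
                n_genotyped_per_sex=400, n_moet_heifers=40,
                horizon_years=20, burn_in_years=10, replicates=5)
            self.link = dataclasses.replace(self.link, horizons=(10, 20))
        return self

    # -- round-trippable plain-text form ------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["link"]["horizons"] = list(self.link.horizons)
        d["link"]["scenarios"] = list(self.link.scenarios)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a plain dict: the preset fills in defaults, explicit
        sections in the dict override them field by field."""
        d = dict(d)
        base = cls(preset=d.get("preset", "paper")).apply_preset()
        try:
            for name in ("founders", "herd", "scheme", "link"):
                if name in d:
                    sec = dict(d.pop(name))
                    if name == "link":
                        if "horizons" in sec:
                            sec["horizons"] = tuple(sec["horizons"])
                        if "scenarios" in sec:
                            sec["scenarios"] = tuple(sec["scenarios"])
                    setattr(base, name,
                            dataclasses.replace(getattr(base, name), **sec))
            for key, val in d.items():
                if not hasattr(base, key):
                    raise ConfigError(f"unknown config key {key!r}")
                setattr(base, key, val)
            return base
        except TypeError as exc:
            raise ConfigError(f"malformed config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(d or {})

    def digest(self) -> str:
        """Short hash of the full configuration, for the run log."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
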