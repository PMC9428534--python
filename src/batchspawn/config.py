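"""Configuration loading, validation, output writing, and run manifests.

Configurations are plain key-value files (TOML or YAML) with sections
mirroring the model modules. Every unset value falls back to the default
study conditions: the six environmental forcing rates, three fishing
mortalities, the 45 cm size limit, the 0.15/0.1 natural-mortality rates,
the 1.13e-6 egg-to-recruit survival, the 3.5 expression noise, 66%
maturation threshold, 25-year lifespan, 5000/100/300/500-year phases,
2000 founders and 50 replicates. Outputs are CSV; a JSON manifest records
the config snapshot, seeds and file checksums so any cell can be re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import (
    DEFAULT_CARRYING_CAPACITY_KG,
    E_GRID,
    F_GRID,
    ScenarioConfig,
    derive_seed,
    factorial_design,
)
from .genetics import ExpressionParams
from .life_history import MortalityParams

__all__ = ["FullConfig", "RunManifest", "load_config", "save_config", "write_outputs"]


@dataclass(frozen=True)
class FullConfig:
    """Validated run configuration: model constants plus the factorial design."""

    # [genetics]
    n_loci: int = 10
    allele_freq: float = 0.5
    noise_sd: float = 3.5
    intercept_cm: float = 60.0
    slope_cm_per_score: float = 2.0
    growth_alpha: float = 0.3533
    growth_beta: float = -0.65
    # [life_history]
    m_immature: float = 0.15
    reproductive_cost: float = 0.1
    juvenile_age_cutoff: int = 3
    max_age: int = 25
    # [reproduction]
    cost_slope: float = 0.00523
    egg_to_recruit: float = 1.13e-6
    # [fishing]
    min_size_cm: float = 45.0
    stop_fraction: float = 0.15
    # [engine]
    burn_in_years: int = 5000
    pre_fishing_years: int = 100
    max_fishing_years: int = 300
    total_experiment_years: int = 500
    initial_abundance: int = 2000
    carrying_capacity_kg: float = DEFAULT_CARRYING_CAPACITY_KG
    theta: float = 1.0
    burn_in_thin: int = 50
    # [design]
    strategies: tuple = ("MBS", "SBS")
    e_grid: tuple = E_GRID
    f_grid: tuple = F_GRID
    replicates: int = 50
    master_seed: int = 1
    allow_extrapolation: bool = False

    def __post_init__(self) -> None:
        if not self.allow_extrapolation:
            bad_e = [e for e in self.e_grid if e not in E_GRID]
            if bad_e:
                raise ValueError(
                    f"env_forcing values {bad_e} lie outside the tested grid "
                    f"{E_GRID}; set allow_extrapolation to override"
                )
            bad_f = [f for f in self.f_grid if f not in F_GRID]
            if bad_f:
                raise ValueError(
                    f"fishing_F values {bad_f} lie outside the tested grid "
                    f"{F_GRID}; set allow_extrapolation to override"
                )
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")
        # delegate range validation to the parameter dataclasses
        self.expression()
        self.mortality()

    def expression(self) -> ExpressionParams:
        return ExpressionParams(
            noise_sd=self.noise_sd,
            intercept_cm=self.intercept_cm,
            slope_cm_per_score=self.slope_cm_per_score,
            growth_alpha=self.growth_alpha,
            growth_beta=self.growth_beta,
        )

    def mortality(self) -> MortalityParams:
        return MortalityParams(
            m_immature=self.m_immature,
            reproductive_cost=self.reproductive_cost,
            juvenile_age_cutoff=self.juvenile_age_cutoff,
            max_age=self.max_age,
        )

    def design(self) -> list[ScenarioConfig]:
        """Expand the configuration into the full factorial scenario list."""
        return factorial_design(
            self.master_seed,
            replicates=self.replicates,
            strategies=tuple(self.strategies),
            e_grid=tuple(self.e_grid),
            f_grid=tuple(self.f_grid),
            burn_in_years=self.burn_in_years,
            pre_fishing_years=self.pre_fishing_years,
            max_fishing_years=self.max_fishing_years,
            total_experiment_years=self.total_experiment_years,
            initial_abundance=self.initial_abundance,
            carrying_capacity_kg=self.carrying_capacity_kg,
            theta=self.theta,
            n_loci=self.n_loci,
            allele_freq=self.allele_freq,
            expression=self.expression(),
            mortality=self.mortality(),
            burn_in_thin=self.burn_in_thin,
        )

    def to_dict(self) -> dict:
        sections = {
            "genetics": [
                "n_loci", "allele_freq", "noise_sd", "intercept_cm",
                "slope_cm_per_score", "growth_alpha", "growth_beta",
            ],
            "life_history": [
                "m_immature", "reproductive_cost", "juvenile_age_cutoff", "max_age",
            ],
            "reproduction": ["cost_slope", "egg_to_recruit"],
            "fishing": ["min_size_cm", "stop_fraction"],
            "engine": [
                "burn_in_years", "pre_fishing_years", "max_fishing_years",
                "total_experiment_years", "initial_abundance",
                "carrying_capacity_kg", "theta", "burn_in_thin",
            ],
            "design": [
                "strategies", "e_grid", "f_grid", "replicates", "master_seed",
                "allow_extrapolation",
            ],
        }
        out: dict = {}
        for section, names in sections.items():
            out[section] = {
                n: (list(v) if isinstance(v := getattr(self, n), tuple) else v)
                for n in names
            }
        return out


_FIELD_NAMES = {f.name for f in dataclasses.fields(FullConfig)}


def _from_sections(data: dict, source: str) -> FullConfig:
    flat: dict = {}
    for section, values in (data or {}).items():
        if not isinstance(values, dict):
            raise ValueError(f"{source}: top level must be sections, got key {section!r}")
        for name, value in values.items():
            if name not in _FIELD_NAMES:
                raise ValueError(f"{source}: unknown parameter {section}.{name}")
            flat[name] = tuple(value) if isinstance(value, list) else value
    return FullConfig(**flat)


def load_config(path: "str | Path | None" = None) -> FullConfig:
    """Load and validate a TOML/YAML configuration; missing file → defaults.

    Any parameter left unset takes its default study value, so an empty
    configuration expands to the full 36-scenario design.
    """
    if path is None:
        return FullConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return _from_sections(data or {}, str(path))


def save_config(cfg: FullConfig, path: "str | Path") -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seeds, and output checksums."""

    config: dict
    master_seed: int
    version: str = __version__
    cell_seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    @classmethod
    def from_config(cls, cfg: FullConfig) -> "RunManifest":
        seeds = {}
        for s in cfg.strategies:
            for e in cfg.e_grid:
                for f in cfg.f_grid:
                    for rep in range(cfg.replicates):
                        key = f"{s}_E{e:g}_F{f:g}_r{rep}"
                        seeds[key] = derive_seed(cfg.master_seed, s, e, f, rep)
        return cls(config=cfg.to_dict(), master_seed=cfg.master_seed, cell_seeds=seeds)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    records: pd.DataFrame,
    cohorts: pd.DataFrame,
    manifest: RunManifest,
    out_dir: "str | Path",
) -> dict:
    """Write the tidy records/cohorts CSVs and a checksummed manifest.

    Returns the file inventory (name → sha256), which is also embedded in
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = {}
    for name, frame in (("records.csv", records), ("cohorts.csv", cohorts)):
        path = out / name
        frame.to_csv(path, index=False)
        inventory[name] = _sha256(path)
    manifest.files = inventory
    (out / "manifest.json").write_text(manifest.to_json())
    return inventory
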