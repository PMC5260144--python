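"""Declarative simulation configuration, YAML round-trip and run manifests.

The schema is strict: unknown keys are rejected, so a typo in a config file
fails loudly instead of silently running defaults.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError


class InjectionEvent(BaseModel):
    """Place ``amount`` tokens of one species uniformly at random over the
    lattice during step ``step`` (step 0: before the first census)."""

    model_config = ConfigDict(extra="forbid")

    step: int = Field(ge=0)
    species: Literal["Ag", "IFNg", "IL4", "IL10", "Ab"]
    amount: int = Field(ge=0)
    has_lps: bool = False


class RuleOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    probabilities: dict[int, float] = Field(default_factory=dict)
    phenotype_gated_secretion: bool = True
    bcell_activates_helpers: bool = False
    r11_duplicates_h2: bool = True
    ifng_consumed_on_activation: bool = False


class SimulationConfig(BaseModel):
    """Everything that determines one replicate; seed fully fixes the run.

    Defaults describe the standard study volume: a dense 9^3 periodic
    lattice carrying 500 macrophages and 2500 lymphocytes (the ~5:1
    lymphocyte:monocyte ratio of a normal human differential white-cell
    count; ~4 cells per site, a crowded tissue-like packing), 800 steps at
    24 steps per simulated day.
    """

    model_config = ConfigDict(extra="forbid")

    L: int = Field(default=9, ge=1)
    n_steps: int = Field(default=800, ge=0)
    seed: int = Field(default=0, ge=0)
    k: int = Field(default=1, ge=1, description="GRN updates per lattice step")

    n_macrophages: int = Field(default=500, ge=0)
    n_bcells: int = Field(default=625, ge=0)
    n_h1: int = Field(default=625, ge=0)
    n_h2: int = Field(default=625, ge=0)
    n_hr: int = Field(default=625, ge=0)

    injections: list[InjectionEvent] = Field(default_factory=list)

    ag_replication_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    ag_site_capacity: int = Field(default=50, ge=1)
    cytokine_half_life: float = Field(default=20.0, gt=0.0)
    antibody_half_life: float = Field(default=40.0, gt=0.0)
    steps_per_day: int = Field(default=24, ge=1)

    helper_innate_activation: float = Field(
        default=0.001, ge=0.0, le=1.0,
        description="per-step probability that a resting helper cell is "
                    "transiently activated by innate (antigen-independent) stimulation")
    lymphocyte_expansion_limit: Optional[float] = Field(
        default=8.0, gt=0.0,
        description="homeostatic cap on lymphocyte proliferation, as a fold "
                    "multiple of the initial B+helper total; None disables it")
    site_capacity: Optional[int] = Field(default=None, ge=1)
    rules: RuleOptions = Field(default_factory=RuleOptions)
    network_path: Optional[str] = None
    audit: bool = True
    output_path: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for ev in self.injections:
            if ev.step > self.n_steps:
                raise ValueError(f"injection at step {ev.step} beyond n_steps={self.n_steps}")
        return self

    # ------------------------------------------------------------------ io
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True),
            encoding="utf-8",
        )

    def hash(self) -> str:
        payload = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration; unknown keys are an error."""
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        return SimulationConfig.model_validate(data)
    except Exception as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
@dataclass
class RunManifest:
    """Provenance of one run: two runs with equal manifests (timestamps
    aside) produce byte-identical outputs."""

    seed: int
    config_hash: str
    network_hash: str
    rule_table_hash: str
    version: str
    created: str = field(compare=False, default="")

    @classmethod
    def build(cls, config: SimulationConfig, network_hash: str, rule_table_hash: str) -> "RunManifest":
        from . import __version__

        return cls(
            seed=config.seed,
            config_hash=config.hash(),
            network_hash=network_hash,
            rule_table_hash=rule_table_hash,
            version=__version__,
            created=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n", encoding="utf-8")
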