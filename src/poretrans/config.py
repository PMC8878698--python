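"""Validated campaign configuration (YAML, schema-checked, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .lattice import PoreGeometry
from .mover import MoveConfig
from .runner import GridSpec


class ConfigError(ValueError):
    """Invalid or malformed configuration file."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    phi_cis: int = Field(ge=2)
    phi_trans: int = Field(ge=2)
    length: int = Field(ge=1)
    metric: Literal["euclidean", "chebyshev"] = "euclidean"

    def to_geometry(self) -> PoreGeometry:
        return PoreGeometry(self.phi_cis, self.phi_trans, self.length)


class GridSection(_Strict):
    phi_cis_values: list[int] = Field(default=[3, 4, 6, 8, 12], min_length=1)
    phi_trans_values: list[int] = Field(default=[3, 4, 6, 8, 12], min_length=1)
    lengths: list[int] = Field(default=[5, 10, 15, 20, 25, 50, 75, 100], min_length=1)
    sample_size: int = Field(default=1000, ge=1)
    attempt_budget_factor: int = Field(default=50, ge=1)


class MoverSection(_Strict):
    n_segments: int = Field(default=100, ge=2)
    bias_direction: float = Field(default=0.05, ge=0.0, lt=1.0)
    bias_selection: float = Field(default=0.5, ge=0.0)
    neighborhood: Literal["moore", "von_neumann"] = "moore"
    max_moves: int = Field(default=10_000_000, ge=1)

    def to_move_config(self, metric: str = "euclidean", seed: int | None = None) -> MoveConfig:
        return MoveConfig(
            n_segments=self.n_segments,
            bias_direction=self.bias_direction,
            bias_selection=self.bias_selection,
            neighborhood=self.neighborhood,
            max_moves=self.max_moves,
            metric=metric,
            seed=seed,
        )


class AnalysisSection(_Strict):
    gof_test: Literal["cramer_von_mises", "anderson_darling"] = "cramer_von_mises"
    gof_bootstrap: int = Field(default=500, ge=0)
    regression_response: Literal["TAU_MEAN", "LOG_SIGMA"] = "TAU_MEAN"
    log_base: Literal["e", "10"] = "e"


class CampaignConfig(_Strict):
    """Top-level configuration tying simulator and statistics together."""

    geometry: GeometrySection | None = None
    grid: GridSection = GridSection()
    mover: MoverSection = MoverSection()
    analysis: AnalysisSection = AnalysisSection()
    output_dir: str = "poretrans-out"
    seed: int = 0
    verbosity: int = 0

    def grid_spec(self) -> GridSpec:
        metric = self.geometry.metric if self.geometry is not None else "euclidean"
        return GridSpec(
            phi_cis_values=tuple(self.grid.phi_cis_values),
            phi_trans_values=tuple(self.grid.phi_trans_values),
            lengths=tuple(self.grid.lengths),
            sample_size=self.grid.sample_size,
            move_config=self.mover.to_move_config(metric=metric),
            base_seed=self.seed,
            attempt_budget_factor=self.grid.attempt_budget_factor,
        )


def load_config(path: str | Path) -> CampaignConfig:
    """Load and validate a YAML campaign configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return CampaignConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"{path}: invalid configuration:\n  " + "\n  ".join(lines)) from exc


def default_config_yaml() -> str:
    """The full default configuration, as a YAML document."""
    cfg = CampaignConfig(geometry=GeometrySection(phi_cis=6, phi_trans=3, length=15))
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)
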