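"""Run configuration: schema-validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class GeneratorConfig(BaseModel):
    """Synthetic aggregation-trajectory parameters (see synthetic module)."""

    model_config = ConfigDict(extra="forbid")

    n_peptides: int = Field(27, ge=1)
    box_edge: float = Field(104.0, gt=0)
    grid_spacing: float = Field(25.0, gt=0)
    sequence: str | None = None  # default: derived from label
    label: str = "Wild"
    step_size: float = Field(2.5, gt=0)
    rotation_deg: float = Field(10.0, ge=0)
    drift: float = Field(1.0, ge=0)
    stick_probability: float = Field(1.0, ge=0.0, le=1.0)
    unstick_probability: float = Field(0.0, ge=0.0, le=1.0)
    n_frames: int = Field(100, ge=1)
    stride_ps: float = Field(10.0, gt=0)
    helix_fraction: float = Field(0.0, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """Full pipeline configuration.

    Either ``generator`` or (``topology_path`` + ``trajectory_paths``)
    must be given.  The analysis window defaults to the last 30% of the
    trajectory when bounds are omitted.
    """

    model_config = ConfigDict(extra="forbid")

    # input: files ...
    topology_path: str | None = None
    trajectory_paths: list[str] | None = None
    trajectory_dialect: str = "multi-model-pdb"
    box_edge: float | None = Field(None, gt=0)
    stride_ps: float = Field(10.0, gt=0)
    # ... or generator
    generator: GeneratorConfig | None = None

    window_start_ps: float | None = None
    window_end_ps: float | None = None
    radii_table: str = "bondi"
    hbond_da_cutoff: float = Field(3.9, gt=0)
    hbond_ha_cutoff: float = Field(2.5, gt=0)
    hbond_min_angle: float = Field(90.0, ge=0, le=180)
    sidechain_cutoff: float = Field(5.5, gt=0)
    stacking_cutoff: float = Field(5.0, gt=0)
    nmer_display_threshold: float = Field(0.05, ge=0, le=1)
    msm_lag: int = Field(1, ge=1)
    msm_n_steps: int | None = Field(None, ge=1)
    output_dir: str = "pepagg_out"
    seed: int = 0

    def resolved(self) -> "RunConfig":
        has_files = self.topology_path is not None and self.trajectory_paths
        if not has_files and self.generator is None:
            raise ConfigError(
                ["input: either generator or topology_path + "
                 "trajectory_paths is required"]
            )
        return self


class ConfigError(ValueError):
    """Configuration problems, one message per offending key."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


def validate_config(source) -> RunConfig:
    """Load and validate a YAML/JSON config file (or a plain dict).

    Raises :class:`ConfigError` listing every offending key; unknown keys
    are errors.
    """
    if isinstance(source, dict):
        data = source
    else:
        data = yaml.safe_load(Path(source).read_text())
    if data is None:
        data = {}
    try:
        cfg = RunConfig(**data)
    except ValidationError as err:
        problems = []
        for e in err.errors():
            loc = ".".join(str(x) for x in e["loc"]) or "<root>"
            problems.append(f"{loc}: {e['msg']}")
        raise ConfigError(problems) from None
    return cfg.resolved()
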