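"""Run configuration: schema, validation, and construction of domain objects.

A run config is a YAML or JSON document with three sections (``scene``,
``sim``, ``analysis``) plus a mandatory global ``seed`` and an output
directory.  Validation is strict: unknown keys are rejected by name and all
schema violations are reported at once.

The global seed feeds independent per-stage generators through fixed
offsets (scene = seed + 1, trace = seed + 2), so each stage is reproducible
on its own without coupling the stages' random streams.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import io as alio
from .scene import (ConfigurationError, GeometryParams, Scene, SceneMedium,
                    SlabSpec, SphereSpec, generate_packed_sphere_slab,
                    make_single_cell_scene)
from .tracer import SimConfig

__all__ = ["RunConfig", "load_config"]

SCENE_SEED_OFFSET = 1
TRACE_SEED_OFFSET = 2


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MediumCfg(_Model):
    """Either a relative index ``m`` (with ``n_out``) or both absolute indices."""

    m: Optional[float] = Field(None, gt=0)
    n_out: float = Field(1.36, ge=1.0)
    n_in: Optional[float] = Field(None, gt=0)

    @model_validator(mode="after")
    def _one_of(self):
        if (self.m is None) == (self.n_in is None):
            raise ValueError("medium needs exactly one of: m, n_in")
        return self

    def build(self) -> SceneMedium:
        n_in = self.n_in if self.n_in is not None else self.m * self.n_out
        return SceneMedium(n_out=self.n_out, n_in=n_in)


class SlabCfg(_Model):
    x_extent: float = Field(gt=0)
    y_extent: float = Field(gt=0)
    thickness: float = Field(gt=0)

    def build(self) -> SlabSpec:
        return SlabSpec(self.x_extent, self.y_extent, self.thickness)


class PackedSlabCfg(_Model):
    type: Literal["packed_slab"]
    slab: SlabCfg
    lattice_counts: Tuple[int, int, int]
    mean_diameter: float = Field(60.0, gt=0)
    diameter_halfwidth: float = Field(10.0, ge=0)
    jitter_fraction: float = Field(0.3, ge=0, lt=1)
    medium: MediumCfg

    def build(self, seed: int) -> Scene:
        params = GeometryParams(lattice_counts=self.lattice_counts,
                                mean_diameter=self.mean_diameter,
                                diameter_halfwidth=self.diameter_halfwidth,
                                jitter_fraction=self.jitter_fraction,
                                seed=seed)
        return generate_packed_sphere_slab(params, self.slab.build(),
                                           self.medium.build())


class SingleSphereCfg(_Model):
    type: Literal["single_sphere"]
    diameter: float = Field(60.0, gt=0)
    medium: MediumCfg
    downstream_margin: Optional[float] = Field(None, gt=0)

    def build(self, seed: int) -> Scene:
        import numpy as np
        shape = SphereSpec(center=np.zeros(3), radius=self.diameter / 2.0)
        return make_single_cell_scene(shape, self.medium.build(),
                                      downstream_margin=self.downstream_margin)


class MaskSceneCfg(_Model):
    type: Literal["mask"]
    mask_path: str
    medium: MediumCfg
    downstream_margin: Optional[float] = Field(None, gt=0)

    @model_validator(mode="after")
    def _exists(self):
        if not Path(self.mask_path).exists():
            raise ValueError(f"mask_path does not exist: {self.mask_path}")
        return self

    def build(self, seed: int) -> Scene:
        mask = alio.read_mask(self.mask_path)
        return make_single_cell_scene(mask, self.medium.build(),
                                      downstream_margin=self.downstream_margin)


class BeamCfg(_Model):
    radius: float = Field(gt=0)
    center: Optional[Tuple[float, float]] = None


class SimCfg(_Model):
    step_mm: float = Field(1e-3, gt=0)
    n_rays: int = Field(1_000_000, ge=1)
    max_steps: Optional[int] = Field(None, ge=1)
    grid_pitch: float = Field(2.0, gt=0)
    beam: Optional[BeamCfg] = None

    def build(self, seed: int) -> SimConfig:
        return SimConfig(step_mm=self.step_mm, n_rays=self.n_rays, seed=seed,
                         max_steps=self.max_steps, grid_pitch=self.grid_pitch,
                         beam_center=self.beam.center if self.beam else None,
                         beam_radius=self.beam.radius if self.beam else None)


class AnalysisCfg(_Model):
    min_prominence: float = Field(0.1, gt=0, le=1)
    min_separation_um: float = Field(20.0, gt=0)
    profile_radius_um: float = Field(10.0, gt=0)
    profile_center: Optional[Tuple[float, float]] = None  # default: slab centre
    smooth_window: int = Field(3, ge=1)


class RunConfig(_Model):
    """Validated top-level run configuration."""

    seed: int
    output_dir: str = "results/run"
    scene: Union[PackedSlabCfg, SingleSphereCfg, MaskSceneCfg] = Field(
        discriminator="type")
    sim: SimCfg = SimCfg()
    analysis: AnalysisCfg = AnalysisCfg()

    def build_scene(self) -> Scene:
        return self.scene.build(self.seed + SCENE_SEED_OFFSET)

    def build_sim_config(self) -> SimConfig:
        return self.sim.build(self.seed + TRACE_SEED_OFFSET)


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  {loc}: {err['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_config(source) -> RunConfig:
    """Load and validate a run config from a YAML/JSON file path, raw text,
    or an already-parsed mapping.

    Raises
    ------
    ConfigurationError
        Listing every offending field at once; unknown keys are named.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = str(source)
        p = Path(text)
        if "\n" not in text and p.exists():
            text = p.read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration must be a mapping")
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigurationError(_format_errors(exc)) from None
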