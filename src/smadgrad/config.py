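"""Schema-validated run configuration (YAML or JSON on disk)."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryCfg(_Strict):
    sphere_radius_um: float = 300.0
    cap_angle_rad: float = float(np.pi / 2)
    shell_thickness_um: float = 40.0
    nucleus_radius_um: float = 4.0
    n_nuclei: int = 800


class GradientCfg(_Strict):
    amplitude: float = 100.0
    decay_length_um: float = 80.0
    baseline: float = 10.0


class OpticsCfg(_Strict):
    pixel_size_um: float = 1.0
    z_spacing_um: float = 2.0
    psf_sigma_xy_um: float = 0.5
    psf_sigma_z_um: float = 1.5
    bleed_fraction: float = 0.15
    attenuation_length_um: float = 150.0


class NoiseCfg(_Strict):
    enabled: bool = True
    photon_scale: float = 2.0
    read_noise_sd: float = 2.0


class SimulateCfg(_Strict):
    z_halfdepth_um: float = 30.0
    pad_um: float = 10.0
    nuclear_brightness: float = 100.0


class SegmentationCfg(_Strict):
    blur_sigma_px: float = 5.0
    window_px: int = 31
    offset: Optional[float] = None
    offset_k: float = 3.0
    offset_min: float = 1.0
    min_area_px: int = 25
    max_area_px: int = 200
    measure_on_raw: bool = True
    subtract_background: bool = True
    corrections_file: Optional[str] = None


class ContourCfg(_Strict):
    n_central_slices: int = 10
    center_slice: Optional[int] = None       # None: argmax nucleus count; simulated runs pin the mid-plane
    cloud_slices: Literal["all", "central"] = "all"
    min_sep_fraction: float = 0.2
    curvature_window_um: float = 40.0
    band_radius_um: Optional[float] = None   # None: auto ladder
    sg_window_pts: Optional[int] = None
    sg_polyorder: int = 3


class AnalysisCfg(_Strict):
    bin_width_um: float = 20.0
    normalization: Literal["none", "nuclear_ratio", "embryo_median"] = "none"
    ratio_scale: Optional[float] = None      # None: simulator nuclear brightness when simulating, else 1
    n_boot: int = 1000
    ci_level: float = 0.95


class ConditionCfg(_Strict):
    name: str
    n_embryos: int = 1
    gradient: GradientCfg = Field(default_factory=GradientCfg)
    stacks: list[str] = Field(default_factory=list)  # input TIFFs when not simulating


class RunConfig(_Strict):
    """Every tunable of a pipeline run; a resolved copy is written to the output directory."""

    seed: int = 0
    simulate: bool = True
    conditions: list[ConditionCfg] = Field(
        default_factory=lambda: [ConditionCfg(name="default")])
    geometry: GeometryCfg = Field(default_factory=GeometryCfg)
    optics: OpticsCfg = Field(default_factory=OpticsCfg)
    noise: NoiseCfg = Field(default_factory=NoiseCfg)
    simulation: SimulateCfg = Field(default_factory=SimulateCfg)
    segmentation: SegmentationCfg = Field(default_factory=SegmentationCfg)
    contour: ContourCfg = Field(default_factory=ContourCfg)
    analysis: AnalysisCfg = Field(default_factory=AnalysisCfg)
    write_figures: bool = True
    overwrite: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if not self.simulate:
            for c in self.conditions:
                if not c.stacks:
                    raise ValueError(
                        f"condition {c.name!r}: input stacks required when simulate=false")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def dump_config(config: RunConfig, path) -> None:
    """Write the fully-resolved configuration (defaults merged) as YAML."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
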