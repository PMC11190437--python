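"""Configuration models for the transition-fibre screen pipeline.

All spatial quantities are in nanometres unless the field name says pixels.
Configs are pydantic models: they validate on construction, round-trip to
JSON losslessly, and publish a JSON schema (``PipelineConfig.model_json_schema()``).
"""
from __future__ import annotations

from typing import Literal, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator


class SceneConfig(BaseModel):
    """Geometry and noise model of one rendered dual-channel scene.

    Defaults emulate a widefield system with a 100x / NA 1.46 objective and a
    6.5 um camera pixel: 65 nm/px sample-plane pixels and a Gaussian PSF of
    sigma = 0.21 * lambda / NA ~ 73 nm for green emission (510 nm).
    """

    model_config = ConfigDict(frozen=True)

    image_size_px: Tuple[int, int] = Field(
        default=(48, 48), description="(height, width) in pixels"
    )
    pixel_size_nm: float = Field(default=65.0, gt=0)
    psf_sigma_nm: float = Field(default=73.4, gt=0)
    background_level: float = Field(
        default=5.0, ge=0, description="expected background photons per pixel"
    )
    read_noise_sd: float = Field(
        default=2.0, ge=0, description="SD of additive Gaussian camera noise"
    )
    seed: int = Field(default=0, ge=0)

    @field_validator("image_size_px")
    @classmethod
    def _positive_size(cls, v: Tuple[int, int]) -> Tuple[int, int]:
        if len(v) != 2 or v[0] <= 0 or v[1] <= 0:
            raise ValueError("image_size_px must be a pair of positive integers")
        return tuple(int(x) for x in v)


class DetectionConfig(BaseModel):
    """Peak-detection settings per channel (prominence thresholds in photons)."""

    model_config = ConfigDict(frozen=True)

    prominence_green: float = Field(default=50.0, gt=0)
    prominence_red: float = Field(default=50.0, gt=0)
    window_px: int = Field(
        default=15, ge=3, description="odd fit-window side length, ~1 um at 65 nm/px"
    )

    @field_validator("window_px")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("window_px must be odd")
        return v


class GeometryConfig(BaseModel):
    """Parameters of the distance and pseudo-diameter measurements."""

    model_config = ConfigDict(frozen=True)

    cutoff_nm: float = Field(
        default=500.0, gt=0, description="max green-to-red pairing distance"
    )
    half_length_nm: float = Field(default=600.0, gt=0)
    step_nm: float = Field(default=16.25, gt=0, description="line-profile sampling step")
    diameter_scale: float = Field(
        default=1.0,
        gt=0,
        description="effective diameter = diameter_scale * fitted Gaussian SD",
    )
    max_effective_diameter_nm: float = Field(
        default=500.0, gt=0, description="per-line outlier bound on effective diameter"
    )


class ProteinSpec(BaseModel):
    """One synthetic tagged protein in the demo screen.

    ``offset_nm`` is the distance of the green structure from the SAS-6
    (red) focus; ``shape`` is 'point' for a focus-like protein or 'ring'
    for an annular transition-fibre-like structure of ``diameter_nm``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    role: Literal["candidate", "poc5_control", "tzp150_control", "bbp136_control"] = (
        "candidate"
    )
    shape: Literal["point", "ring"] = "point"
    offset_nm: float = Field(ge=0)
    diameter_nm: float = Field(default=0.0, ge=0)
    amplitude: float = Field(default=3000.0, gt=0)


def default_demo_proteins() -> list[ProteinSpec]:
    """Three controls plus one ring-like transition-fibre candidate.

    Offsets place POC5 just distal to SAS-6 (proximal gate), TZP150 at the
    transition zone (distal gate) and the candidate in between with an
    annulus wider than the point-like basal-body control BBP136.
    """
    return [
        ProteinSpec(name="POC5", role="poc5_control", shape="point", offset_nm=250.0),
        ProteinSpec(name="BBP136", role="bbp136_control", shape="point", offset_nm=350.0),
        ProteinSpec(name="TZP150", role="tzp150_control", shape="point", offset_nm=450.0),
        ProteinSpec(
            name="TFP270",
            role="candidate",
            shape="ring",
            offset_nm=350.0,
            diameter_nm=340.0,
        ),
    ]


class PipelineConfig(BaseModel):
    """End-to-end configuration of the ``screen`` command."""

    model_config = ConfigDict(frozen=True)

    scene: SceneConfig = Field(default_factory=SceneConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    proteins: list[ProteinSpec] = Field(default_factory=default_demo_proteins)
    n_cells: int = Field(default=12, ge=2, description="cells imaged per protein")
    alpha: float = Field(default=0.05, ge=0, le=1)
    seed: int = Field(default=1, ge=0)
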