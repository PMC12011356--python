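"""Validated run configuration (YAML) and builders for the domain objects.

A :class:`RunConfig` fully determines one simulate → reconstruct → evaluate
run: probe, rotation sweep, beam model, phantom, SAF parameters, output
voxel grid and the seed.  Configs validate against the declared schema on
load (unknown fields are rejected), and every run writes its fully
resolved form, plus a short content hash, beside its outputs so paired
volumes can be checked for shared provenance.
"""

from __future__ import annotations

import hashlib
import json
from typing import Annotated, Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .forward_sim import BeamModel, Phantom, make_cyst_phantom, make_point_phantom
from .geometry import Frame, RotationSequence, ScanGrid, TransducerSpec, grid_for_depth
from .saf_core import SAFConfig, Volume3D

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = {"extra": "forbid"}


class TransducerCfg(_Strict):
    speed_of_sound: float = 1490.0
    center_frequency: float = 10e6
    sampling_frequency: float = 40e6
    n_elements: int = 68
    pitch: float = 0.2
    element_width: float = 0.15
    element_height: float = 8.0
    elev_focal_depth: float = 45.0

    def build(self) -> TransducerSpec:
        return TransducerSpec(**self.model_dump())


class RotationCfg(_Strict):
    start: float = 0.0
    stop: float = 179.0  # inclusive
    step: float = 1.0

    def build(self) -> RotationSequence:
        angles = np.arange(self.start, self.stop + self.step / 2.0, self.step)
        return RotationSequence(angles, self.step)


class BeamCfg(_Strict):
    elev_focal_depth: float | None = None  # None: use the probe focus
    f_number_below: float | None = None  # None: focal depth / element height
    f_number_above: float | None = None
    sensitivity_window: Literal["gaussian", "hann", "rect"] = "gaussian"
    pulse_cycles: int = 2
    pulse_fractional_bandwidth: float = 0.6
    beam_waist: float | None = None

    def build(self, spec: TransducerSpec) -> BeamModel:
        fn = spec.elev_f_number
        return BeamModel(
            elev_focal_depth=self.elev_focal_depth or spec.elev_focal_depth,
            f_number_below=self.f_number_below or fn,
            f_number_above=self.f_number_above or fn,
            sensitivity_window=self.sensitivity_window,
            pulse_cycles=self.pulse_cycles,
            pulse_fractional_bandwidth=self.pulse_fractional_bandwidth,
            beam_waist=self.beam_waist,
        )


class PointPhantomCfg(_Strict):
    kind: Literal["point"] = "point"
    position: tuple[float, float, float]

    def build(self, seed: int) -> Phantom:
        return make_point_phantom(self.position)


class CystPhantomCfg(_Strict):
    kind: Literal["cyst"] = "cyst"
    center: tuple[float, float, float]
    diameter: float = 6.0
    block_side: float = 20.0
    n_scatterers: int = 10_000

    def build(self, seed: int) -> Phantom:
        return make_cyst_phantom(
            self.center, self.diameter, self.block_side, self.n_scatterers, seed
        )


PhantomCfg = Annotated[Union[PointPhantomCfg, CystPhantomCfg], Field(discriminator="kind")]


class GridCfg(_Strict):
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    spacing: float = 0.2

    def build(self) -> Volume3D:
        return Volume3D.empty(self.shape, self.spacing, self.origin, Frame())


class SAFCfg(_Strict):
    focal_depth: float | None = None
    f_number_below: float | None = None
    f_number_above: float | None = None
    apodization_window: Literal["hann", "hamming", "rect"] = "hann"
    interpolation: Literal["linear", "nearest"] = "linear"
    signal_mode: Literal["coherent_rf", "coherent_iq", "incoherent_envelope"] = (
        "incoherent_envelope"
    )
    normalization: Literal["weight_sum", "angle_count", "none"] = "weight_sum"
    lateral_weight_floor: float | None = None  # None: one lateral pixel

    def build(self, spec: TransducerSpec) -> SAFConfig:
        fn = spec.elev_f_number
        return SAFConfig(
            focal_depth=self.focal_depth or spec.elev_focal_depth,
            f_number_below=self.f_number_below or fn,
            f_number_above=self.f_number_above or fn,
            apodization_window=self.apodization_window,
            interpolation=self.interpolation,
            signal_mode=self.signal_mode,
            normalization=self.normalization,
            lateral_weight_floor=(
                self.lateral_weight_floor if self.lateral_weight_floor is not None else spec.pitch
            ),
        )


class RunConfig(_Strict):
    """Schema-validated description of one end-to-end run."""

    seed: int = 0
    mode: Literal["rf", "iq", "envelope"] = "rf"
    max_depth: float | None = None  # axial data range; None: derived from the grid
    transducer: TransducerCfg = TransducerCfg()
    rotation: RotationCfg = RotationCfg()
    beam: BeamCfg = BeamCfg()
    saf: SAFCfg = SAFCfg()
    phantom: PhantomCfg
    output_grid: GridCfg

    @model_validator(mode="after")
    def _positive_grid(self) -> "RunConfig":
        if any(n < 1 for n in self.output_grid.shape):
            raise ValueError("output_grid.shape entries must be >= 1")
        return self

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            payload = yaml.safe_load(f)
        return cls.model_validate(payload)

    def resolved(self) -> dict:
        return json.loads(self.model_dump_json())

    def resolved_json(self) -> str:
        return json.dumps(self.resolved(), sort_keys=True, indent=2)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]

    # -- builders -----------------------------------------------------------
    def build_spec(self) -> TransducerSpec:
        return self.transducer.build()

    def build_sequence(self) -> RotationSequence:
        return self.rotation.build()

    def build_beam(self) -> BeamModel:
        return self.beam.build(self.build_spec())

    def build_saf(self) -> SAFConfig:
        return self.saf.build(self.build_spec())

    def build_phantom(self, seed: int | None = None) -> Phantom:
        return self.phantom.build(self.seed if seed is None else seed)

    def build_grid(self) -> ScanGrid:
        spec = self.build_spec()
        if self.max_depth is not None:
            depth = self.max_depth
        else:
            g = self.output_grid
            depth = g.origin[2] + g.shape[2] * (
                g.spacing if np.isscalar(g.spacing) else g.spacing
            ) + 2.0
        return grid_for_depth(spec, depth)

    def build_template(self) -> Volume3D:
        return self.output_grid.build()
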