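"""Coordinate frames, rotation and scan-grid relations for rotational 3D ultrasound.

Conventions used throughout the package
---------------------------------------
* Axes: lateral = +x, elevational = +y, axial (depth, increasing away from
  the transducer face) = +z.
* The probe rotates about the axial axis through the array centre; positive
  angles are counter-clockwise when viewed from the transducer.
* Angles are **degrees** at every public interface and radians internally.
* Physical coordinates are millimetres; indices are 0-based.
* Reconstruction (voxel) grids place voxel centres at
  ``origin + (index + 0.5) * spacing``.
* Slice grids follow the acquisition convention instead: axial sample ``j``
  lies at depth ``j * sa`` and lateral column ``i`` is centred at
  ``(i - (Ni - 1) / 2) * sle`` — a signed lateral coordinate that is zero on
  the rotation axis.  A slice therefore spans the full lateral aperture of
  the array, with the rotation axis through its middle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransducerSpec",
    "ScanGrid",
    "RotationSequence",
    "Frame",
    "rotation_matrix",
    "world_to_slice",
    "slice_to_world",
    "make_grid",
    "grid_for_depth",
]


@dataclass(frozen=True)
class TransducerSpec:
    """Physical and acquisition parameters of a 1D linear array.

    The defaults describe the elevation-focused 68-element, 10 MHz array
    used throughout the package's worked examples.

    Units: ``speed_of_sound`` m/s, frequencies Hz, all lengths mm.
    """

    speed_of_sound: float = 1490.0
    center_frequency: float = 10e6
    sampling_frequency: float = 40e6
    n_elements: int = 68
    pitch: float = 0.2
    element_width: float = 0.15
    element_height: float = 8.0
    elev_focal_depth: float = 45.0

    def __post_init__(self) -> None:
        for name in (
            "speed_of_sound",
            "center_frequency",
            "sampling_frequency",
            "pitch",
            "element_width",
            "element_height",
            "elev_focal_depth",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"TransducerSpec.{name} must be strictly positive")
        if self.n_elements < 1:
            raise ValueError("TransducerSpec.n_elements must be >= 1")
        if not self.sampling_frequency > 2 * self.center_frequency:
            raise ValueError("sampling_frequency must exceed twice center_frequency")

    @property
    def c_mm(self) -> float:
        """Speed of sound in mm/s."""
        return self.speed_of_sound * 1e3

    @property
    def wavelength_mm(self) -> float:
        return self.c_mm / self.center_frequency

    @property
    def axial_sample_mm(self) -> float:
        """Depth covered by one axial sample (two-way travel)."""
        return self.c_mm / (2.0 * self.sampling_frequency)

    @property
    def elev_f_number(self) -> float:
        """f-number of the fixed elevational focus (focal depth / element height)."""
        return self.elev_focal_depth / self.element_height


@dataclass(frozen=True)
class ScanGrid:
    """Sampling grid of a beamformed slice (and its elevational expansion).

    ``sle`` is the lateral/elevational length per pixel (equal to the element
    pitch), ``sa`` the axial length per sample.  ``ni``/``nr`` equal the
    element count; ``nj`` is taken from the recorded data length.
    """

    sle: float
    sa: float
    ni: int
    nj: int
    nr: int

    def __post_init__(self) -> None:
        if self.sle <= 0 or self.sa <= 0:
            raise ValueError("grid spacings must be strictly positive")
        if self.ni < 1 or self.nj < 1 or self.nr < 1:
            raise ValueError("grid sample counts must be >= 1")

    @property
    def L(self) -> float:
        """Lateral extent in mm."""
        return self.ni * self.sle

    @property
    def A(self) -> float:
        """Axial extent in mm."""
        return self.nj * self.sa

    @property
    def E(self) -> float:
        """Elevational extent in mm."""
        return self.nr * self.sle

    # -- index <-> physical coordinate maps ---------------------------------
    def lateral_mm(self, i):
        """Signed lateral coordinate of column ``i`` (0 on the rotation axis)."""
        return (np.asarray(i, dtype=float) - (self.ni - 1) / 2.0) * self.sle

    def lateral_index(self, l):
        """Fractional column index of signed lateral coordinate ``l`` (mm)."""
        return np.asarray(l, dtype=float) / self.sle + (self.ni - 1) / 2.0

    def axial_mm(self, j):
        return np.asarray(j, dtype=float) * self.sa

    def axial_index(self, a):
        return np.asarray(a, dtype=float) / self.sa


def make_grid(spec: TransducerSpec, n_axial_samples: int) -> ScanGrid:
    """Build the slice grid implied by a transducer spec.

    Lateral/elevational spacing equals the element pitch, axial spacing
    follows from the speed of sound and the sampling rate, and the lateral
    and elevational pixel counts equal the element count.  The axial sample
    count is dictated by the recorded data, not by the probe.
    """
    if not isinstance(spec, TransducerSpec):
        raise TypeError("spec must be a TransducerSpec")
    if n_axial_samples < 1:
        raise ValueError("n_axial_samples must be >= 1")
    return ScanGrid(
        sle=spec.pitch,
        sa=spec.c_mm / (2.0 * spec.sampling_frequency),
        ni=spec.n_elements,
        nj=int(n_axial_samples),
        nr=spec.n_elements,
    )


def grid_for_depth(spec: TransducerSpec, max_depth_mm: float) -> ScanGrid:
    """Slice grid whose axial range covers at least ``max_depth_mm``."""
    if max_depth_mm <= 0:
        raise ValueError("max_depth_mm must be positive")
    n = int(math.ceil(max_depth_mm / spec.axial_sample_mm)) + 1
    return make_grid(spec, n)


@dataclass(frozen=True)
class RotationSequence:
    """Ordered list of acquisition angles (degrees) with their nominal step."""

    angles: np.ndarray
    step: float

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("RotationSequence.angles must be a nonempty 1D list")
        if np.any(angles < 0) or np.any(angles >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if self.step <= 0:
            raise ValueError("step must be positive")
        object.__setattr__(self, "angles", angles)

    @classmethod
    def half_turn(cls, step: float = 1.0, start: float = 0.0) -> "RotationSequence":
        """The default sweep: ``start`` to ``start + 180 - step`` in ``step``-degree
        increments (180 slices at 1 degree)."""
        return cls(np.arange(start, start + 180.0, step), step)

    def __len__(self) -> int:
        return int(self.angles.size)


_DEFAULT_CONVENTION = (
    "x=lateral, y=elevational, z=axial(depth); theta CCW about +z viewed from probe"
)


@dataclass(frozen=True)
class Frame:
    """World frame: the rotation centre and the fixed axis convention."""

    rotation_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    convention: str = _DEFAULT_CONVENTION

    def __post_init__(self) -> None:
        rc = np.asarray(self.rotation_center, dtype=float)
        if rc.shape != (3,):
            raise ValueError("rotation_center must be a 3-vector")
        object.__setattr__(self, "rotation_center", rc)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """Right-handed rotation about the axial (+z) axis by ``theta_deg`` degrees."""
    t = math.radians(float(theta_deg))
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def world_to_slice(point, theta_deg: float, frame: Frame | None = None) -> np.ndarray:
    """Map world points to slice-frame coordinates ``(l, e, a)`` at angle ``theta``.

    Applies the inverse rotation to ``point - rotation_center``.  ``l`` and
    ``e`` are signed; the axial coordinate is unchanged by the rotation.
    Accepts a single 3-vector or an ``(n, 3)`` array.
    """
    rc = np.zeros(3) if frame is None else frame.rotation_center
    p = np.asarray(point, dtype=float) - rc
    t = math.radians(float(theta_deg))
    c, s = math.cos(t), math.sin(t)
    out = np.empty_like(p)
    out[..., 0] = p[..., 0] * c + p[..., 1] * s
    out[..., 1] = -p[..., 0] * s + p[..., 1] * c
    out[..., 2] = p[..., 2]
    return out


def slice_to_world(lea, theta_deg: float, frame: Frame | None = None) -> np.ndarray:
    """Exact inverse of :func:`world_to_slice`."""
    rc = np.zeros(3) if frame is None else frame.rotation_center
    q = np.asarray(lea, dtype=float)
    t = math.radians(float(theta_deg))
    c, s = math.cos(t), math.sin(t)
    out = np.empty_like(q)
    out[..., 0] = q[..., 0] * c - q[..., 1] * s
    out[..., 1] = q[..., 0] * s + q[..., 1] * c
    out[..., 2] = q[..., 2]
    return out + rc
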