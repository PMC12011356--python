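"""Virtual-source forward simulator for rotational 3D ultrasound.

Generates the per-angle beamformed slice data that the reconstruction
consumes.  The acoustic model treats the fixed elevational focus of the
array as a virtual point source: a scatterer sitting off the imaging plane
at elevation ``e`` and depth ``a`` is detected in-plane at the *apparent*
depth ``F ± sqrt(e² + (a − F)²)`` — below the focal depth ``F`` the echo
arrives late (``+``), above it early (``−``).  The detected amplitude is
tapered by an elevational sensitivity window whose support grows with the
distance from the focus (constant-f-number aperture growth, floored at the
diffraction-limited beam waist so the focal plane itself keeps a finite
thickness).  Each detection deposits a Gaussian-windowed tone burst at the
carrier frequency into the nearest lateral columns of the slice.

This geometric model is the exact adjoint of the back-projection performed
by :mod:`rotsaf.saf_core`, which gives reconstruction tests an analyzable
ground truth.  It deliberately ignores attenuation, refraction, multiple
scattering and in-plane diffraction; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .geometry import Frame, RotationSequence, ScanGrid, TransducerSpec, world_to_slice

__all__ = [
    "Phantom",
    "BeamModel",
    "SliceStack",
    "make_point_phantom",
    "make_cyst_phantom",
    "apparent_axial_position",
    "simulate_scan",
]

_MODES = ("rf", "iq", "envelope")


@dataclass(frozen=True)
class Phantom:
    """Point scatterers in the world frame: positions (mm) and amplitudes."""

    positions: np.ndarray
    amplitudes: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        amp = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if pos.shape != (amp.size, 3):
            raise ValueError("positions must be (n, 3) with matching amplitudes")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return int(self.amplitudes.size)


def make_point_phantom(position) -> Phantom:
    """Single unit-amplitude scatterer at ``position = (x, y, z)`` mm."""
    p = np.asarray(position, dtype=float)
    if p.shape != (3,):
        raise ValueError("position must be a 3-vector")
    if p[2] <= 0:
        raise ValueError("point target depth must be strictly positive")
    return Phantom(p[None, :], np.ones(1), meta={"kind": "point", "position": p.tolist()})


def make_cyst_phantom(
    center,
    diameter: float,
    block_side: float = 20.0,
    n_scatterers: int = 10_000,
    seed: int = 0,
) -> Phantom:
    """Speckle block with an anechoic spherical cyst.

    Scatterer positions are uniform in a cube of side ``block_side`` around
    ``center``; amplitudes are drawn from a normal distribution centred on
    0.5 (sd 0.25) truncated to [0, 1], and zeroed inside the cyst sphere.
    """
    if diameter <= 0 or block_side <= 0:
        raise ValueError("diameter and block_side must be positive")
    if diameter >= block_side:
        raise ValueError("cyst diameter must be smaller than the block side")
    c = np.asarray(center, dtype=float)
    if c.shape != (3,):
        raise ValueError("center must be a 3-vector")
    rng = np.random.default_rng(seed)
    pos = c + rng.uniform(-block_side / 2.0, block_side / 2.0, size=(int(n_scatterers), 3))
    amp = stats.truncnorm.rvs(-2.0, 2.0, loc=0.5, scale=0.25, size=int(n_scatterers), random_state=rng)
    inside = np.linalg.norm(pos - c, axis=1) <= diameter / 2.0
    amp[inside] = 0.0
    return Phantom(
        pos,
        amp,
        seed=seed,
        meta={
            "kind": "cyst",
            "center": c.tolist(),
            "diameter": float(diameter),
            "block_side": float(block_side),
            "n_scatterers": int(n_scatterers),
        },
    )


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the virtual-source beam replacing a full wave simulation.

    ``f_number_below``/``f_number_above`` control the elevational acceptance
    on either side of the focal depth ``F`` (mm): the half-aperture at depth
    ``a`` is ``|a − F| / (2 f#)``, floored at half the beam waist
    (``beam_waist``; ``None`` selects the diffraction scale ``λ·f#``).
    The pulse is a ``pulse_cycles``-cycle Gaussian-windowed tone burst whose
    envelope width follows ``pulse_fractional_bandwidth`` (−6 dB, Gaussian
    spectrum).
    """

    elev_focal_depth: float = 45.0
    f_number_below: float = 5.625
    f_number_above: float = 5.625
    sensitivity_window: str = "gaussian"
    pulse_cycles: int = 2
    pulse_fractional_bandwidth: float = 0.6
    beam_waist: float | None = None

    def __post_init__(self) -> None:
        if self.elev_focal_depth <= 0:
            raise ValueError("elev_focal_depth must be positive")
        if self.f_number_below <= 0 or self.f_number_above <= 0:
            raise ValueError("f-numbers must be positive")
        if self.sensitivity_window not in ("gaussian", "hann", "rect"):
            raise ValueError(f"unknown sensitivity_window {self.sensitivity_window!r}")
        if self.pulse_cycles < 1 or self.pulse_fractional_bandwidth <= 0:
            raise ValueError("pulse parameters must be positive")
        if self.beam_waist is not None and self.beam_waist <= 0:
            raise ValueError("beam_waist must be positive when given")

    @classmethod
    def from_spec(cls, spec: TransducerSpec, **kwargs: Any) -> "BeamModel":
        """Beam matched to the hardware: focus at ``R`` and f-number ``R/h``."""
        kwargs.setdefault("elev_focal_depth", spec.elev_focal_depth)
        kwargs.setdefault("f_number_below", spec.elev_f_number)
        kwargs.setdefault("f_number_above", spec.elev_f_number)
        return cls(**kwargs)

    def waist_mm(self, spec: TransducerSpec) -> float:
        if self.beam_waist is not None:
            return self.beam_waist
        return spec.wavelength_mm * self.f_number_below

    def acceptance_limit(self, a, spec: TransducerSpec):
        """Elevational half-aperture (mm) at depth ``a``, waist-floored."""
        a_rel = np.asarray(a, dtype=float) - self.elev_focal_depth
        geom = np.where(
            a_rel >= 0,
            a_rel / (2.0 * self.f_number_below),
            (-a_rel) / (2.0 * self.f_number_above),
        )
        return np.maximum(geom, 0.5 * self.waist_mm(spec))


def _sensitivity(u: np.ndarray, window: str) -> np.ndarray:
    """Elevational sensitivity on ``u = |e| / e_max`` in [0, 1]."""
    if window == "gaussian":
        return np.exp(-2.0 * u * u)  # sigma = e_max / 2
    if window == "hann":
        return 0.5 * (1.0 + np.cos(np.pi * u))
    if window == "rect":
        return np.ones_like(u)
    raise ValueError(f"unknown sensitivity window {window!r}")


def apparent_axial_position(a, e, F: float):
    """In-plane depth at which an off-plane scatterer is detected.

    Below the focus the echo path through the virtual source lengthens the
    round trip (``F + sqrt(e² + (a−F)²)``); above it the relation mirrors
    through the lateral-elevational plane (``F − sqrt(...)``).
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(a <= 0):
        raise ValueError("axial position must be strictly positive")
    d = np.sqrt(e * e + (a - F) * (a - F))
    out = np.where(a >= F, F + d, F - d)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SliceStack:
    """Per-angle beamformed slices ``S_detect(l, a, θ)`` with grid metadata.

    ``data`` has shape ``(n_angles, n_lateral, n_axial)``; ``mode`` is one of
    ``rf`` (real), ``iq`` (complex analytic) or ``envelope`` (nonnegative).
    """

    data: np.ndarray
    mode: str
    grid: ScanGrid
    angles: RotationSequence
    spec: TransducerSpec
    frame: Frame = field(default_factory=Frame)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        data = np.asarray(self.data)
        expected = (len(self.angles), self.grid.ni, self.grid.nj)
        if data.shape != expected:
            raise ValueError(f"data shape {data.shape} inconsistent with {expected}")
        if self.mode == "envelope" and np.any(data < 0):
            raise ValueError("envelope-mode samples must be nonnegative")
        if self.mode == "iq" and not np.iscomplexobj(data):
            raise ValueError("iq-mode data must be complex")
        object.__setattr__(self, "data", data)


def simulate_scan(
    phantom: Phantom,
    seq: RotationSequence,
    spec: TransducerSpec,
    beam: BeamModel,
    grid: ScanGrid,
    mode: str = "rf",
    frame: Frame | None = None,
) -> SliceStack:
    """Simulate the rotational acquisition of ``phantom``.

    For every angle each scatterer is transformed to the slice frame; if its
    elevation is inside the beam's acceptance at its depth, a tone burst is
    deposited at the apparent axial position, linearly split across the two
    nearest lateral columns and scaled by amplitude × elevational
    sensitivity.  An empty phantom yields an all-zero stack.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if len(seq) == 0:
        raise ValueError("angle list must be nonempty")
    if grid.ni != spec.n_elements or not np.isclose(grid.sle, spec.pitch):
        raise ValueError("grid is inconsistent with the transducer spec")
    frame = frame or Frame()

    F = beam.elev_focal_depth
    c_mm = spec.c_mm
    f0 = spec.center_frequency
    bw = beam.pulse_fractional_bandwidth
    # Gaussian envelope: -6 dB fractional bandwidth bw of a Gaussian spectrum.
    sigma_t = math.sqrt(2.0 * math.log(2.0)) / (math.pi * bw * f0)
    sigma_a = sigma_t * c_mm / 2.0
    half_width = beam.pulse_cycles * c_mm / (2.0 * f0)  # depth support of the burst
    k_wave = 4.0 * math.pi * f0 / c_mm  # phase per mm of two-way depth offset
    waist = beam.waist_mm(spec)

    K = int(math.ceil(half_width / grid.sa))
    offs = np.arange(-K, K + 1)

    out = np.zeros((len(seq), grid.ni, grid.nj), dtype=np.complex128)
    pos, amp = phantom.positions, phantom.amplitudes
    if len(phantom) > 0:
        for k, th in enumerate(seq.angles):
            lea = world_to_slice(pos, th, frame)
            l, e, a = lea[:, 0], lea[:, 1], lea[:, 2]
            valid = a > 0
            a_rel = a - F
            e_geom = np.where(
                a_rel >= 0,
                a_rel / (2.0 * beam.f_number_below),
                (-a_rel) / (2.0 * beam.f_number_above),
            )
            e_lim = np.maximum(e_geom, 0.5 * waist)
            u = np.abs(e) / e_lim
            valid &= u <= 1.0
            w = amp * _sensitivity(u, beam.sensitivity_window)
            valid &= w > 0
            idx = np.flatnonzero(valid)
            if idx.size == 0:
                continue
            d_vs = np.sqrt(e[idx] ** 2 + a_rel[idx] ** 2)
            a_app = np.where(a_rel[idx] >= 0, F + d_vs, F - d_vs)
            fi = grid.lateral_index(l[idx])
            i0 = np.floor(fi).astype(np.int64)
            di = fi - i0
            j0 = np.floor(a_app / grid.sa).astype(np.int64)
            jj = j0[:, None] + offs[None, :]
            d = jj * grid.sa - a_app[:, None]
            envl = np.exp(-0.5 * (d / sigma_a) ** 2)
            envl[np.abs(d) > half_width] = 0.0
            pulse = w[idx, None] * envl * np.exp(1j * (k_wave * d))
            jok = (jj >= 0) & (jj < grid.nj)
            jj_c = np.clip(jj, 0, grid.nj - 1)
            buf = out[k]
            for cols, lw in ((i0, 1.0 - di), (i0 + 1, di)):
                cok = (cols >= 0) & (cols < grid.ni)
                contrib = np.where(jok & cok[:, None], lw[:, None] * pulse, 0.0)
                np.add.at(buf, (np.clip(cols, 0, grid.ni - 1)[:, None], jj_c), contrib)

    if mode == "rf":
        data = out.real.copy()
    elif mode == "iq":
        data = out
    else:
        data = np.abs(out)
    meta = {
        "beam": {
            "elev_focal_depth": F,
            "f_number_below": beam.f_number_below,
            "f_number_above": beam.f_number_above,
            "sensitivity_window": beam.sensitivity_window,
            "pulse_cycles": beam.pulse_cycles,
            "pulse_fractional_bandwidth": bw,
            "beam_waist": waist,
        },
        "phantom": dict(phantom.meta),
        "seed": phantom.seed,
    }
    return SliceStack(data, mode, grid, seq, spec, frame, meta)
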