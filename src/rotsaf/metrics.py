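"""Resolution and contrast metrics: MIP, circular profiles, FWHM, CNR.

The circumferential resolution of a rotationally acquired point target is
measured on a maximum-intensity projection (MIP) by sampling the image
along a circle centred on the rotation axis through the target, and taking
the full width at half maximum (FWHM) of that profile along the arc.
Contrast is measured as the contrast-to-noise ratio (CNR)

    CNR = (mu_target - mu_background) / sqrt(var_target + var_background)

between a window inside the target and one in the adjacent background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .saf_core import Volume3D

__all__ = [
    "ProjectionImage",
    "CircularProfile",
    "CNRWindows",
    "mip",
    "plane_image",
    "circular_profile",
    "fwhm",
    "cnr",
    "cyst_cnr_windows",
    "improvement_rate",
]

_AXES = {"lateral": 0, "elevational": 1, "axial": 2}


@dataclass(frozen=True)
class ProjectionImage:
    """2D image with physical pixel geometry (mm).

    Pixel centres sit at ``origin + (index + 0.5) * spacing`` per axis;
    ``axes`` names the two retained volume axes.
    """

    data: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float]
    axes: tuple[str, str]

    def pixel_index(self, point_mm) -> np.ndarray:
        p = np.asarray(point_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5


@dataclass(frozen=True)
class CircularProfile:
    """Intensity sampled along a circle; positions are arc length in mm."""

    intensities: np.ndarray
    arc_positions: np.ndarray
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        y = np.asarray(self.intensities, dtype=float)
        s = np.asarray(self.arc_positions, dtype=float)
        if y.shape != s.shape or y.ndim != 1 or y.size < 8:
            raise ValueError("profile needs matching 1D arrays of >= 8 samples")
        ds = np.diff(s)
        if not np.allclose(ds, ds[0]):
            raise ValueError("arc spacing must be uniform")
        object.__setattr__(self, "intensities", y)
        object.__setattr__(self, "arc_positions", s)

    @property
    def arc_spacing(self) -> float:
        return float(self.arc_positions[1] - self.arc_positions[0])


def mip(volume: Volume3D, axis) -> ProjectionImage:
    """Maximum-intensity projection of a volume along one axis."""
    if not isinstance(volume, Volume3D):
        raise TypeError("volume must be a Volume3D")
    if volume.values.size == 0:
        raise ValueError("cannot project an empty volume")
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be lateral/elevational/axial or 0/1/2")
    keep = [i for i in range(3) if i != ax]
    names = {v: k for k, v in _AXES.items()}
    return ProjectionImage(
        volume.values.max(axis=ax),
        (float(volume.spacing[keep[0]]), float(volume.spacing[keep[1]])),
        (float(volume.origin[keep[0]]), float(volume.origin[keep[1]])),
        (names[keep[0]], names[keep[1]]),
    )


def plane_image(volume: Volume3D, axis, coordinate_mm: float) -> ProjectionImage:
    """Extract the 2D section nearest ``coordinate_mm`` along ``axis``.

    ``axis='elevational'`` gives a B-scan (lateral × axial), ``axis='axial'``
    a C-scan (lateral × elevational).
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    centers = volume.axis_centers(ax)
    i = int(np.argmin(np.abs(centers - coordinate_mm)))
    keep = [k for k in range(3) if k != ax]
    names = {v: k for k, v in _AXES.items()}
    data = np.take(volume.values, i, axis=ax)
    return ProjectionImage(
        data,
        (float(volume.spacing[keep[0]]), float(volume.spacing[keep[1]])),
        (float(volume.origin[keep[0]]), float(volume.origin[keep[1]])),
        (names[keep[0]], names[keep[1]]),
    )


def circular_profile(
    image: ProjectionImage, center, radius: float, n_samples: int = 720
) -> CircularProfile:
    """Sample ``image`` bilinearly along a circle of ``radius`` mm.

    Angles are uniformly spaced over a full turn; arc positions are
    ``radius × angle``.  Raises if the circle leaves the image.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, dtype=float)
    ang = np.linspace(0.0, 2.0 * math.pi, int(n_samples), endpoint=False)
    pts = c[None, :] + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    px = image.pixel_index(pts)  # (n, 2) fractional pixel indices
    n0, n1 = image.data.shape
    if (
        px[:, 0].min() < 0
        or px[:, 1].min() < 0
        or px[:, 0].max() > n0 - 1
        or px[:, 1].max() > n1 - 1
    ):
        raise ValueError("circular path exits the image bounds")
    vals = map_coordinates(np.asarray(image.data, dtype=float), px.T, order=1, mode="nearest")
    return CircularProfile(vals, radius * ang, (float(c[0]), float(c[1])), float(radius))


def fwhm(profile, spacing: float | None = None) -> float:
    """Full width at half maximum of an intensity profile, in mm.

    The baseline is the profile minimum (circular profiles over speckle
    never reach zero), so the half level is halfway between minimum and
    maximum.  Crossings bracketing the global peak are located with
    sub-sample linear interpolation.  A :class:`CircularProfile` is treated
    as periodic; a plain 1D array needs ``spacing`` and raises if the peak
    is not resolved inside the array.
    """
    if isinstance(profile, CircularProfile):
        y = profile.intensities.copy()
        ds = profile.arc_spacing
        circular = True
    else:
        y = np.asarray(profile, dtype=float)
        if spacing is None:
            raise TypeError("spacing is required for plain 1D profiles")
        ds = float(spacing)
        circular = False
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    base = float(y.min())
    top = float(y.max())
    if top <= base:
        raise ValueError("profile is flat; FWHM undefined")
    half = 0.5 * (top + base)
    p = int(np.argmax(y))
    if circular:
        shift = y.size // 2 - p
        y = np.roll(y, shift)
        p = y.size // 2
    i = p
    while i >= 0 and y[i] > half:
        i -= 1
    if i < 0:
        raise ValueError("half-maximum not crossed left of the peak; width unresolvable")
    xl = i + (half - y[i]) / (y[i + 1] - y[i])
    j = p
    n = y.size
    while j < n and y[j] > half:
        j += 1
    if j >= n:
        raise ValueError("half-maximum not crossed right of the peak; width unresolvable")
    xr = (j - 1) + (y[j - 1] - half) / (y[j - 1] - y[j])
    return float((xr - xl) * ds)


@dataclass(frozen=True)
class CNRWindows:
    """Disjoint boolean masks selecting the target and background regions."""

    target: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.target, dtype=bool)
        b = np.asarray(self.background, dtype=bool)
        if t.shape != b.shape:
            raise ValueError("target and background masks must share a shape")
        if not t.any() or not b.any():
            raise ValueError("both regions must be nonempty")
        if (t & b).any():
            raise ValueError("target and background regions must be disjoint")
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "background", b)


def cnr(data, windows: CNRWindows) -> float:
    """Contrast-to-noise ratio between the two windowed regions."""
    arr = data.data if isinstance(data, ProjectionImage) else np.asarray(data, dtype=float)
    if isinstance(data, ProjectionImage):
        arr = np.asarray(arr, dtype=float)
    t = arr[windows.target]
    b = arr[windows.background]
    denom = float(t.var() + b.var())
    if denom <= 0:
        raise ValueError("zero total variance; CNR undefined")
    return float((t.mean() - b.mean()) / math.sqrt(denom))


def cyst_cnr_windows(image: ProjectionImage, center, diameter: float) -> CNRWindows:
    """Default windows for a cyst of ``diameter`` mm centred at ``center``.

    Target: a disc of half the cyst diameter.  Background: an equal-area
    annulus starting at 1.5× the cyst radius, safely outside the boundary.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    c = np.asarray(center, dtype=float)
    r_t = diameter / 4.0
    r_in = 1.5 * (diameter / 2.0)
    r_out = math.sqrt(r_in * r_in + r_t * r_t)
    n0, n1 = image.data.shape
    x = image.origin[0] + (np.arange(n0) + 0.5) * image.spacing[0]
    y = image.origin[1] + (np.arange(n1) + 0.5) * image.spacing[1]
    R = np.sqrt((x[:, None] - c[0]) ** 2 + (y[None, :] - c[1]) ** 2)
    return CNRWindows(R <= r_t, (R >= r_in) & (R <= r_out))


def improvement_rate(before: float, after: float, kind: str) -> float:
    """Percent improvement of a metric after processing.

    FWHM improves by shrinking, CNR by growing; both are reported relative
    to the value before processing.
    """
    if before <= 0:
        raise ValueError("'before' must be strictly positive")
    if kind == "fwhm":
        return (before - after) / before * 100.0
    if kind == "cnr":
        return (after - before) / before * 100.0
    raise ValueError("kind must be 'fwhm' or 'cnr'")
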