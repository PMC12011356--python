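"""Persistence: HDF5 slice stacks and volumes, NIfTI export, phantoms, PNGs.

Container layouts
-----------------
Slice stack (HDF5): datasets ``/data`` (angle × lateral × axial) and
``/angles`` (degrees); attributes ``mode``, ``step``, JSON-encoded ``grid``,
``spec``, ``frame`` and ``meta``, and a ``format_version``.

Volume (HDF5): datasets ``/values`` and ``/weights``; attributes
``spacing``, ``origin`` and JSON-encoded ``frame``/``meta``.  Volumes are
also exportable as NIfTI with the voxel spacing in the affine.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .forward_sim import Phantom, SliceStack
from .geometry import Frame, RotationSequence, ScanGrid, TransducerSpec
from .saf_core import Volume3D

__all__ = [
    "SchemaError",
    "write_slice_stack",
    "read_slice_stack",
    "write_volume",
    "read_volume",
    "volume_to_nifti",
    "write_phantom",
    "read_phantom",
    "to_db",
    "save_png",
]

FORMAT_VERSION = 1


class SchemaError(ValueError):
    """A container is missing fields or violates a declared invariant."""


def _dump(obj) -> str:
    return json.dumps(obj, sort_keys=True)


def _frame_dict(frame: Frame) -> dict:
    return {"rotation_center": frame.rotation_center.tolist(), "convention": frame.convention}


def _frame_from(d: dict) -> Frame:
    return Frame(np.asarray(d["rotation_center"]), d["convention"])


def _require(group, names: tuple[str, ...], where: str) -> None:
    for name in names:
        if name not in group:
            raise SchemaError(f"{where}: missing required field '{name}'")


def _require_attrs(obj, names: tuple[str, ...], where: str) -> None:
    for name in names:
        if name not in obj.attrs:
            raise SchemaError(f"{where}: missing required attribute '{name}'")


def write_slice_stack(stack: SliceStack, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data)
        f.create_dataset("angles", data=stack.angles.angles)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["mode"] = stack.mode
        f.attrs["step"] = stack.angles.step
        f.attrs["grid"] = _dump(dataclasses.asdict(stack.grid))
        f.attrs["spec"] = _dump(dataclasses.asdict(stack.spec))
        f.attrs["frame"] = _dump(_frame_dict(stack.frame))
        f.attrs["meta"] = _dump(stack.meta)


def read_slice_stack(path) -> SliceStack:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _require(f, ("data", "angles"), str(path))
        _require_attrs(f, ("mode", "step", "grid", "spec"), str(path))
        data = f["data"][...]
        angles = RotationSequence(f["angles"][...], float(f.attrs["step"]))
        grid = ScanGrid(**json.loads(f.attrs["grid"]))
        spec = TransducerSpec(**json.loads(f.attrs["spec"]))
        mode = str(f.attrs["mode"])
        frame = _frame_from(json.loads(f.attrs["frame"])) if "frame" in f.attrs else Frame()
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    try:
        return SliceStack(data, mode, grid, angles, spec, frame, meta)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_volume(vol: Volume3D, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=vol.values)
        f.create_dataset("weights", data=vol.weights)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["spacing"] = vol.spacing
        f.attrs["origin"] = vol.origin
        f.attrs["frame"] = _dump(_frame_dict(vol.frame))
        f.attrs["meta"] = _dump(vol.meta)


def read_volume(path) -> Volume3D:
    path = Path(path)
    with h5py.File(path, "r") as f:
        _require(f, ("values", "weights"), str(path))
        _require_attrs(f, ("spacing", "origin"), str(path))
        values = f["values"][...]
        weights = f["weights"][...]
        spacing = np.asarray(f.attrs["spacing"])
        origin = np.asarray(f.attrs["origin"])
        frame = _frame_from(json.loads(f.attrs["frame"])) if "frame" in f.attrs else Frame()
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    try:
        return Volume3D(values, weights, spacing, origin, frame, meta)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def volume_to_nifti(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI; spacing and origin live in the affine (mm)."""
    import nibabel as nib

    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin + 0.5 * vol.spacing  # first voxel centre
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_phantom(phantom: Phantom, path) -> None:
    """One scatterer per line (x y z amplitude) plus a JSON sidecar."""
    path = Path(path)
    table = np.column_stack([phantom.positions, phantom.amplitudes])
    np.savetxt(path, table, header="x_mm y_mm z_mm amplitude")
    sidecar = {"seed": phantom.seed, "meta": phantom.meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True, indent=2))


def read_phantom(path) -> Phantom:
    path = Path(path)
    table = np.atleast_2d(np.loadtxt(path))
    if table.shape[1] != 4:
        raise SchemaError(f"{path}: expected 4 columns (x y z amplitude)")
    seed, meta = None, {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        seed, meta = d.get("seed"), d.get("meta", {})
    return Phantom(table[:, :3], table[:, 3], seed=seed, meta=meta)


def to_db(values, dynamic_range_db: float = 20.0) -> np.ndarray:
    """Log-compress to dB relative to the maximum, clipped to the range."""
    v = np.asarray(values, dtype=float)
    peak = v.max()
    if peak <= 0:
        raise ValueError("cannot log-compress a nonpositive image")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(v / peak)
    return np.clip(db, -abs(dynamic_range_db), 0.0)


def save_png(image, path, dynamic_range_db: float = 20.0) -> None:
    """Save a (projection) image as a log-compressed grayscale PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = image.data if hasattr(image, "data") else np.asarray(image)
    db = to_db(data, dynamic_range_db)
    plt.imsave(str(path), db.T, cmap="gray", vmin=-abs(dynamic_range_db), vmax=0.0, origin="lower")
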