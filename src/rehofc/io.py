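"""NIfTI-1 and motion-trace I/O built on nibabel.

Volumes are stored as plain NIfTI-1 (.nii or .nii.gz); motion traces as
rp-style whitespace text with six numeric columns (three translations in mm,
three rotations in radians). Stat maps get a JSON sidecar carrying kind,
parameters and degenerate-voxel flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BrainMask, ImageGrid, MotionTrace, StatMap, Volume4D

__all__ = [
    "read_bold_nifti",
    "write_bold_nifti",
    "read_stat_nifti",
    "write_stat_nifti",
    "read_motion_trace",
    "write_motion_trace",
    "read_mask_nifti",
    "write_mask_nifti",
]


class DimensionalityError(ValueError):
    """Image does not have the expected number of dimensions."""


def _grid_from_img(img) -> ImageGrid:
    return ImageGrid(dims=tuple(int(d) for d in img.shape[:3]), affine=np.asarray(img.affine))


def read_bold_nifti(path, tr_override: float | None = None) -> Volume4D:
    """Load a 4D BOLD NIfTI file.

    TR is taken from the header time step (``pixdim[4]``) unless
    *tr_override* is given; a missing/zero header TR falls back to 3.0 s.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionalityError(f"expected a 4D image, got {img.ndim}D: {path}")
    tr = tr_override
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if not np.isfinite(tr) or tr <= 0:
            tr = 3.0
    data = np.asarray(img.dataobj, dtype=np.float64)
    return Volume4D(grid=_grid_from_img(img), data=data, tr_seconds=tr)


def write_bold_nifti(vol: Volume4D, path) -> None:
    hdr = nib.Nifti1Header()
    hdr.set_xyzt_units("mm", "sec")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine, header=hdr)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_stat_nifti(stat: StatMap, path) -> None:
    """Write a stat map as 3D NIfTI (out-of-mask voxels zero) plus JSON sidecar."""
    data = np.where(stat.mask.data, stat.data, 0.0)
    img = nib.Nifti1Image(data.astype(np.float32), stat.grid.affine)
    nib.save(img, str(path))
    sidecar = {"kind": stat.kind, "meta": stat.meta}
    if stat.flags is not None:
        sidecar["n_flagged"] = int(stat.flags.sum())
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))


def read_stat_nifti(path, mask: BrainMask, kind: str | None = None) -> StatMap:
    """Load a 3D stat map onto an existing mask; kind from sidecar unless given."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"expected a 3D image, got {img.ndim}D: {path}")
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        payload = json.loads(sc.read_text())
        kind = kind or payload.get("kind")
        meta = payload.get("meta", {})
    if kind is None:
        raise ValueError(f"stat kind not given and no sidecar found for {path}")
    return StatMap(
        grid=_grid_from_img(img),
        mask=mask,
        kind=kind,
        data=np.asarray(img.dataobj, dtype=np.float64),
        meta=meta,
    )


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_mask_nifti(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_mask_nifti(path) -> BrainMask:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"expected a 3D mask image, got {img.ndim}D: {path}")
    return BrainMask(grid=_grid_from_img(img), data=np.asarray(img.dataobj) > 0)


def read_motion_trace(path, n_expected: int | None = None) -> MotionTrace:
    """Parse an rp-style six-column motion file.

    Columns 1-3 are translations in mm, columns 4-6 rotations in radians.
    """
    try:
        arr = np.loadtxt(str(path), dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in motion file {path}: {exc}") from exc
    if arr.size == 0 or arr.shape[1] != 6:
        raise ValueError(f"motion file must have six numeric columns, got shape {arr.shape}")
    if n_expected is not None and len(arr) != n_expected:
        raise ValueError(f"motion file has {len(arr)} rows, expected {n_expected}")
    return MotionTrace(translations_mm=arr[:, :3], rotations_rad=arr[:, 3:])


def write_motion_trace(trace: MotionTrace, path) -> None:
    arr = np.hstack([trace.translations_mm, trace.rotations_rad])
    np.savetxt(str(path), arr, fmt="%.10g")
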