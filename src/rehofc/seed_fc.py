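"""Seed-based functional connectivity of the default mode network.

A spherical seed (default: 10 mm radius around the precuneus/BA31 center at
MNI (-12, -47, 32)) defines a mean reference series; every in-mask voxel's
Pearson correlation with that series gives the r map, and Fisher's
variance-stabilizing z = arctanh(r) makes the maps approximately normal for
group t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BrainMask, StatMap, Volume4D, sphere_mask

__all__ = ["SeedSpec", "seed_mask", "seed_timeseries", "pearson_map", "fisher_z", "fc_maps"]

DEFAULT_SEED_CENTER_MM = (-12.0, -47.0, 32.0)
DEFAULT_SEED_RADIUS_MM = 10.0

# |r| is clamped to this before arctanh; r = +-1 would map to +-inf
_R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    center_mm: tuple[float, float, float] = DEFAULT_SEED_CENTER_MM
    radius_mm: float = DEFAULT_SEED_RADIUS_MM

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


def seed_mask(grid, spec: SeedSpec, brain: BrainMask) -> BrainMask:
    """Voxels whose center lies within the seed sphere, inside the brain mask."""
    sphere = sphere_mask(grid, spec.center_mm, spec.radius_mm)
    inside = sphere & brain.data
    if not inside.any():
        raise ValueError(
            f"seed at {spec.center_mm} (r={spec.radius_mm} mm) contains no in-brain voxel"
        )
    return BrainMask(grid=grid, data=inside)


def seed_timeseries(vol: Volume4D, seed: BrainMask) -> np.ndarray:
    """Unweighted mean series over the seed voxels."""
    seed.check_same_grid(vol)
    return vol.data[seed.data].mean(axis=0)


def pearson_map(vol: Volume4D, seed_series: np.ndarray, mask: BrainMask) -> StatMap:
    """Pearson correlation of every in-mask voxel with the seed series.

    Constant voxel series get r = 0 and are flagged; a constant seed series
    is a degenerate-seed error.
    """
    mask.check_same_grid(vol)
    s = np.asarray(seed_series, dtype=float)
    if len(s) != vol.n_timepoints:
        raise ValueError("seed series length differs from volume timepoints")
    if vol.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation map")
    sc = s - s.mean()
    s_norm = np.sqrt((sc**2).sum())
    if s_norm < 1e-12 * max(1.0, np.abs(s).max()):
        raise ValueError("seed series is constant")

    X = vol.data[mask.data]  # (n_voxels, n_timepoints)
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    degenerate = x_norm < 1e-12 * np.maximum(1.0, np.abs(X).max(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ sc) / (x_norm * s_norm)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))

    data = np.zeros(vol.grid.dims)
    data[mask.data] = r
    flags = np.zeros(vol.grid.dims, dtype=bool)
    flags[mask.data] = degenerate
    return StatMap(grid=vol.grid, mask=mask, kind="r", data=data, flags=flags)


def fisher_z(r_map: StatMap, legacy_ratio: bool = False) -> StatMap:
    """Fisher r-to-z transform, z = (1/2) ln((1+r)/(1-r)) = arctanh(r).

    r = +-1 is clamped to +-(1 - 1e-7) and flagged. ``legacy_ratio=True``
    computes the plain ratio (1+r)/(1-r) instead — kept only for comparison
    with toolchains that print that form; it is not a z statistic and is not
    suitable for normal-theory group tests.
    """
    if r_map.kind != "r":
        raise ValueError(f"expected an r map, got kind {r_map.kind!r}")
    r = r_map.data[r_map.mask.data]
    clamped = np.abs(r) >= _R_CLAMP
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = (1.0 + r) / (1.0 - r) if legacy_ratio else np.arctanh(r)
    data = np.zeros(r_map.grid.dims)
    data[r_map.mask.data] = z
    flags = np.zeros(r_map.grid.dims, dtype=bool)
    flags[r_map.mask.data] = clamped
    if r_map.flags is not None:
        flags |= r_map.flags
    return StatMap(
        grid=r_map.grid,
        mask=r_map.mask,
        kind="z",
        data=data,
        meta=dict(r_map.meta, transform="legacy_ratio" if legacy_ratio else "arctanh"),
        flags=flags,
    )


def fc_maps(vol: Volume4D, brain: BrainMask, spec: SeedSpec = SeedSpec()) -> tuple[StatMap, StatMap]:
    """Convenience: seed -> mean series -> r map -> z map for one subject."""
    seed = seed_mask(vol.grid, spec, brain)
    series = seed_timeseries(vol, seed)
    r = pearson_map(vol, series, brain)
    r.meta.update(seed_center_mm=list(spec.center_mm), seed_radius_mm=spec.radius_mm,
                  seed_n_voxels=seed.n_inside)
    return r, fisher_z(r)
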