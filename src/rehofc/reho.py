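"""Regional homogeneity: Kendall's coefficient of concordance (KCC) over
voxel neighborhoods.

For each in-mask voxel the time series of the voxel and its neighbors from a
cubic neighborhood (27 = faces+edges+corners by default, 19 or 7 available)
are rank-transformed over time and their concordance

    W = sum_i (R_i - Rbar)^2 * 12 / (K^2 (n^3 - n))

is computed, where R_i is the across-series rank sum at timepoint i,
Rbar = K (n+1) / 2, K the number of series and n the number of timepoints.
W is 1 when all neighborhood series rank the timepoints identically and has
null expectation 1/K for independent series.

Ties receive average ranks; no tie-correction term is applied to the
denominator (BOLD series are continuous, so exact ties are measure-zero).
Neighborhoods are truncated at the mask boundary (effective K < 27) rather
than dropping boundary voxels; truncated voxels are flagged.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .core import BrainMask, StatMap, Volume4D

__all__ = ["rank_timeseries", "kendall_w", "reho_map", "neighborhood_offsets"]


def rank_timeseries(series) -> np.ndarray:
    """Ranks 1..n of a time series, average ranks for ties."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("series must be 1D with length >= 2")
    if not np.isfinite(arr).all():
        raise ValueError("series contains non-finite values")
    return rankdata(arr)


def kendall_w(ranks: np.ndarray) -> float:
    """Kendall's W from a (K, n) matrix of per-series ranks.

    Uses the rank-sum form ``(sum_i R_i^2 - n Rbar^2) / ((1/12) K^2 (n^3-n))``;
    values are clamped to [0, 1] only against floating slop (<= 1e-12).
    """
    R = np.asarray(ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("ranks must be a (K, n) matrix")
    K, n = R.shape
    if K < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={K}, n={n}")
    Ri = R.sum(axis=0)
    Rbar = (n + 1) * K / 2.0
    W = (Ri**2).sum() - n * Rbar**2
    W /= (K**2) * (n**3 - n) / 12.0
    return float(min(max(W, 0.0), 1.0))


_NEIGHBORHOODS = {7: 1, 19: 2, 27: 3}


def neighborhood_offsets(size: int = 27) -> np.ndarray:
    """Integer offsets of the cubic ReHo calculation unit.

    7 = center + faces, 19 = + edges, 27 = + corners (the center voxel is
    included; "one selected voxel and 26 adjacent voxels").
    """
    if size not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    max_sq = _NEIGHBORHOODS[size]
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if i * i + j * j + k * k <= max_sq
    ]
    return np.array(offs, dtype=int)


def reho_map(
    vol: Volume4D, mask: BrainMask, neighborhood: int = 27, standardize: bool = False
) -> StatMap:
    """Per-voxel Kendall's W over the cubic neighborhood, vectorized.

    The ranks of every in-mask voxel's series are computed once; for each
    neighborhood offset the shifted rank field and shifted mask are
    accumulated, which yields the across-series rank sums R_i and the
    effective K (in-mask neighborhood count) at every voxel simultaneously.
    Voxels with effective K < 2 get W = 0 and are flagged, as are truncated
    (K < *neighborhood*) boundary voxels.

    ``standardize=True`` divides by the in-mask mean W ("mReHo"), for
    sensitivity analyses; raw W is the default since group contrasts compare
    raw values.
    """
    mask.check_same_grid(vol)
    n = vol.n_timepoints
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    offsets = neighborhood_offsets(neighborhood)

    inside = mask.data
    ranks = np.zeros_like(vol.data)
    ranks[inside] = rankdata(vol.data[inside], axis=-1)

    dims = vol.grid.dims
    rank_sum = np.zeros(dims + (n,))
    k_eff = np.zeros(dims)
    for off in offsets:
        src_sl, dst_sl = _shift_slices(dims, off)
        rank_sum[dst_sl] += ranks[src_sl] * inside[src_sl][..., None]
        k_eff[dst_sl[:3]] += inside[src_sl]

    K = k_eff
    with np.errstate(divide="ignore", invalid="ignore"):
        Rbar = K * (n + 1) / 2.0
        S = ((rank_sum - Rbar[..., None]) ** 2).sum(axis=-1)
        W = 12.0 * S / (K**2 * (n**3 - n))
    degenerate = inside & (K < 2)
    W = np.where(inside & ~degenerate, W, 0.0)
    W = np.clip(W, 0.0, 1.0)  # floating slop only; exact values already in range

    kind = "W"
    meta = {"neighborhood": neighborhood, "n_timepoints": n}
    if standardize:
        mean_w = W[inside].mean()
        if mean_w <= 0:
            raise ValueError("cannot standardize: in-mask mean W is zero")
        W = np.where(inside, W / mean_w, 0.0)
        kind = "mW"
        meta["standardized_by_mean_w"] = float(mean_w)

    truncated = inside & (K < neighborhood)
    return StatMap(
        grid=vol.grid,
        mask=mask,
        kind=kind,
        data=W,
        meta=meta,
        flags=truncated | degenerate,
    )


def _shift_slices(dims, offset):
    """Slice pairs so that dst[dst_sl] += src[src_sl] shifts src by *offset*."""
    src, dst = [], []
    for d, o in zip(dims, offset):
        if o >= 0:
            src.append(slice(0, d - o))
            dst.append(slice(o, d))
        else:
            src.append(slice(-o, d))
            dst.append(slice(0, d + o))
    return tuple(src), tuple(dst)
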