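"""Group-level voxelwise inference and cluster-extent thresholding.

One- and two-sample Student t-maps over subject stat maps (classical
equal-variance pooled model, df = n_a + n_b - 2), two-tailed p maps,
probability-matched z maps, and connected-component cluster tables in the
style of neuroimaging peak reports: cluster size, hemisphere, peak T, peak Z
and peak mm coordinates.  Thresholding follows the uncorrected
cluster-extent heuristic: voxelwise two-tailed p < 0.001, clusters formed
separately per sign of t, and only components with strictly more than 50
voxels retained.  No familywise correction is applied beyond the extent rule,
and the output metadata says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import BrainMask, StatMap, voxel_to_mm

__all__ = [
    "one_sample_t",
    "two_sample_t",
    "t_to_p",
    "t_to_z",
    "threshold_clusters",
    "cluster_report",
    "ClusterRecord",
    "dice_overlap",
]

DEFAULT_P_THRESH = 0.001
DEFAULT_EXTENT = 50


@dataclass
class ClusterRecord:
    cluster_size_voxels: int
    sign: str  # "increase" | "decrease"
    peak_t: float
    peak_z: float
    peak_mm: tuple[float, float, float]
    peak_index: tuple[int, int, int]
    voxel_indices: np.ndarray = field(repr=False, compare=False)  # (n, 3) int

    @property
    def hemisphere(self) -> str:
        x = self.peak_mm[0]
        return "L" if x < 0 else ("R" if x > 0 else "midline")


def _stack(maps: list[StatMap]) -> tuple[np.ndarray, StatMap]:
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    ref = maps[0]
    for m in maps[1:]:
        if not m.grid.same_geometry(ref.grid) or not np.array_equal(m.mask.data, ref.mask.data):
            raise ValueError("stat maps are on different grids/masks")
    return np.stack([m.values for m in maps], axis=0), ref


def one_sample_t(maps: list[StatMap]) -> StatMap:
    """Voxelwise one-sample t = mean / (sd / sqrt(m)), df = m - 1.

    Voxels with zero sample sd are flagged and get t = 0.
    """
    X, ref = _stack(maps)
    m = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(m))
    t = np.where(degenerate, 0.0, t)
    return _t_map(t, degenerate, ref, df=m - 1, contrast="one_sample")


def two_sample_t(maps_a: list[StatMap], maps_b: list[StatMap]) -> StatMap:
    """Pooled-variance two-sample t per voxel, sign convention a - b.

    With group a = patients and b = controls, decreases in patients come out
    negative.  df = n_a + n_b - 2; zero pooled variance is flagged.
    """
    A, ref = _stack(maps_a)
    B, _ = _stack(maps_b)
    if maps_b[0].grid.same_geometry(ref.grid) is False:
        raise ValueError("group grids differ")
    if not np.array_equal(maps_b[0].mask.data, ref.mask.data):
        raise ValueError("group masks differ")
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    degenerate = se < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=0) - B.mean(axis=0)) / se
    t = np.where(degenerate, 0.0, t)
    return _t_map(t, degenerate, ref, df=na + nb - 2, contrast="a_minus_b")


def _t_map(t_vals, degenerate, ref: StatMap, df: int, contrast: str) -> StatMap:
    data = np.zeros(ref.grid.dims)
    data[ref.mask.data] = t_vals
    flags = np.zeros(ref.grid.dims, dtype=bool)
    flags[ref.mask.data] = degenerate
    return StatMap(
        grid=ref.grid,
        mask=ref.mask,
        kind="t",
        data=data,
        meta={"df": df, "contrast": contrast,
              "inference": "uncorrected cluster-extent (no familywise correction)"},
        flags=flags,
    )


def t_to_p(t_map: StatMap, df: int | None = None) -> StatMap:
    """Two-tailed Student tail probability per voxel."""
    df = _resolve_df(t_map, df)
    t = t_map.data[t_map.mask.data]
    p = 2.0 * stats.t.sf(np.abs(t), df)
    data = np.zeros(t_map.grid.dims)
    data[t_map.mask.data] = np.minimum(p, 1.0)
    return StatMap(grid=t_map.grid, mask=t_map.mask, kind="p", data=data,
                   meta=dict(t_map.meta, df=df), flags=t_map.flags)


def t_to_z(t_map: StatMap, df: int | None = None) -> StatMap:
    """Sign-preserving probability-matched normal quantile of the t statistic.

    z = Phi^-1 of the one-tailed Student tail of |t|, computed on the
    complementary tail (isf of sf) so large |t| stays accurate.
    """
    df = _resolve_df(t_map, df)
    t = t_map.data[t_map.mask.data]
    tail = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(tail) * np.sign(t)
    z = np.where(np.abs(t) < 1e-300, 0.0, z)
    data = np.zeros(t_map.grid.dims)
    data[t_map.mask.data] = z
    return StatMap(grid=t_map.grid, mask=t_map.mask, kind="z", data=data,
                   meta=dict(t_map.meta, df=df), flags=t_map.flags)


def _resolve_df(t_map: StatMap, df) -> int:
    df = df if df is not None else t_map.meta.get("df")
    if df is None or df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return int(df)


_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


def threshold_clusters(
    t_map: StatMap,
    df: int | None = None,
    p_thresh: float = DEFAULT_P_THRESH,
    extent: int = DEFAULT_EXTENT,
    connectivity: int = 26,
    sign: str = "both",
) -> list[ClusterRecord]:
    """Cluster-extent thresholding of a t map.

    Voxels with two-tailed p < *p_thresh* are split by the sign of t; within
    each sign, connected components under the chosen connectivity (6 faces,
    18 +edges, 26 +corners) with strictly more than *extent* voxels are kept.
    Each surviving component yields a record peaked at its maximal-|t| voxel.
    """
    if p_thresh <= 0 or extent < 0:
        raise ValueError("thresholds must be positive")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    if sign not in ("increase", "decrease", "both"):
        raise ValueError("sign must be 'increase', 'decrease' or 'both'")
    df = _resolve_df(t_map, df)
    t_crit = stats.t.isf(p_thresh / 2.0, df)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[connectivity])

    records: list[ClusterRecord] = []
    signs = {"increase": [+1], "decrease": [-1], "both": [+1, -1]}[sign]
    for s in signs:
        supra = t_map.mask.data & (s * t_map.data > t_crit)
        labels, n_lab = ndimage.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            if len(vox) <= extent:
                continue
            t_here = t_map.data[tuple(vox.T)]
            peak_i = int(np.argmax(np.abs(t_here)))
            peak_idx = tuple(int(v) for v in vox[peak_i])
            peak_t = float(t_here[peak_i])
            tail = stats.t.sf(abs(peak_t), df)
            peak_z = float(stats.norm.isf(tail) * np.sign(peak_t))
            peak_mm = tuple(float(c) for c in voxel_to_mm(t_map.grid, peak_idx))
            records.append(
                ClusterRecord(
                    cluster_size_voxels=len(vox),
                    sign="increase" if s > 0 else "decrease",
                    peak_t=peak_t,
                    peak_z=peak_z,
                    peak_mm=peak_mm,
                    peak_index=peak_idx,
                    voxel_indices=vox,
                )
            )
    records.sort(key=lambda r: r.cluster_size_voxels, reverse=True)
    return records


REPORT_COLUMNS = [
    "cluster_size", "hemisphere", "sign", "peak_t", "peak_z",
    "x", "y", "z", "anatomical_label",
]


def cluster_report(records: list[ClusterRecord], contrast: str = "") -> pd.DataFrame:
    """Peak table (TSV-ready): size, hemisphere from the sign of peak x
    (x<0 left, x>0 right, 0 midline), peak T/Z, mm coordinates, and a blank
    free-text anatomical label column; sorted by cluster size descending."""
    rows = [
        {
            "cluster_size": r.cluster_size_voxels,
            "hemisphere": r.hemisphere,
            "sign": r.sign,
            "peak_t": round(r.peak_t, 4),
            "peak_z": round(r.peak_z, 4),
            "x": r.peak_mm[0],
            "y": r.peak_mm[1],
            "z": r.peak_mm[2],
            "anatomical_label": "",
        }
        for r in sorted(records, key=lambda r: r.cluster_size_voxels, reverse=True)
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.attrs["contrast"] = contrast
    return df


def dice_overlap(records: list[ClusterRecord], truth_voxels: np.ndarray, dims) -> float:
    """Dice coefficient between the union of cluster voxels and a ground-truth
    voxel set given as an (n, 3) index array or boolean grid."""
    detected = np.zeros(dims, dtype=bool)
    for r in records:
        detected[tuple(r.voxel_indices.T)] = True
    if truth_voxels.dtype == bool:
        truth = truth_voxels
    else:
        truth = np.zeros(dims, dtype=bool)
        truth[tuple(np.asarray(truth_voxels).T)] = True
    inter = (detected & truth).sum()
    denom = detected.sum() + truth.sum()
    return float(2.0 * inter / denom) if denom else 0.0
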