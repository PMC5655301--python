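"""Synthetic two-group resting-state BOLD cohort with known implanted effects.

Emulates the statistical structure of a patient/control resting-state study
so the full pipeline (preprocess -> ReHo + seed FC -> group t-maps) can be
exercised and validated against ground truth without any scan data:

* a per-subject band-limited (0.01-0.08 Hz) "DMN" signal carried by the
  precuneus seed sphere and by distant DMN node spheres, whose coupling to
  the seed is weaker in "patients";
* band-limited ROI-common signals inside designated spheres that raise
  neighborhood synchrony (hence Kendall's W), with a weaker weight in
  "patients";
* per-voxel linear drift and white noise, and smooth random-walk motion
  traces, with designated subjects violating the 10 mm / 1 degree QC limits.

Seed-coupling differences are implanted variance-preservingly: a DMN-node
voxel receives ``c*d(t) + sqrt(c_max^2 - c^2)*e(t)`` with d the seed-carried
signal and e an independent node signal, so the total coherent power (and
therefore regional homogeneity) is identical in both groups and the groups
differ only in seed correlation.  ReHo spheres conversely carry signals
uncorrelated with the seed, so the two implanted effects are separable.

Everything is deterministic given ``rng_seed``; per-subject substreams are
spawned from one SeedSequence so a subject's data does not depend on
generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BrainMask, ImageGrid, MotionTrace, Volume4D, sphere_mask

__all__ = [
    "SphereROI",
    "CohortSpec",
    "GroundTruth",
    "default_grid",
    "default_brain_mask",
    "band_limited_series",
    "generate_subject",
    "simulate_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class SphereROI:
    center_mm: tuple[float, float, float]
    radius_mm: float = 9.0


def default_grid() -> ImageGrid:
    """Desk-scale 3 mm grid (26 x 30 x 26) whose mm frame contains the
    precuneus seed at (-12, -47, 32); full MNI-size grids are supported but
    not the default."""
    return ImageGrid.isotropic((26, 30, 26), voxel_size_mm=3.0, origin_mm=(-39.0, -89.0, -7.0))


def default_brain_mask(grid: ImageGrid, shrink: float = 0.92) -> BrainMask:
    """Ellipsoidal 'brain' centered in the grid, semi-axes = shrink * half-extent."""
    dims = np.array(grid.dims)
    center = (dims - 1) / 2.0
    semi = shrink * (dims - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    nrm = sum(((g - c) / s) ** 2 for g, c, s in zip((ii, jj, kk), center, semi))
    return BrainMask(grid=grid, data=nrm <= 1.0)


DEFAULT_DMN_ROIS = (
    SphereROI((21.0, -47.0, 32.0), 9.0),
    SphereROI((-12.0, -17.0, 29.0), 9.0),
)
DEFAULT_REHO_ROIS = (
    SphereROI((-21.0, -65.0, 38.0), 9.0),
    SphereROI((12.0, -26.0, 41.0), 9.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation parameters; the defaults define the standard study
    conditions used throughout the test-suite recovery experiments.

    Couplings and local weights are amplitudes relative to the unit-variance
    band-limited signals; ``noise_sd`` = 6 puts the raw voxelwise
    signal-to-noise around 0.1, in the range typical of unsmoothed BOLD.
    Per-subject amplitude jitter provides realistic between-subject variance
    so group t statistics are not driven by sampling noise alone.
    """

    n_patients: int = 20
    n_controls: int = 20
    grid: ImageGrid = field(default_factory=default_grid)
    n_timepoints_acquired: int = 140
    tr_seconds: float = 3.0
    seed_center_mm: tuple[float, float, float] = (-12.0, -47.0, 32.0)
    seed_radius_mm: float = 10.0
    dmn_rois: tuple[SphereROI, ...] = DEFAULT_DMN_ROIS
    fc_coupling_controls: float = 0.85
    fc_coupling_patients: float = 0.40
    fc_coupling_subject_sd: float = 0.06
    reho_effect_rois: tuple[SphereROI, ...] = DEFAULT_REHO_ROIS
    reho_local_weight_controls: float = 0.90
    reho_local_weight_patients: float = 0.40
    reho_weight_subject_sd: float = 0.04
    band_hz: tuple[float, float] = (0.01, 0.08)
    drift_slope_sd: float = 0.03
    noise_sd: float = 6.0
    n_motion_outliers: int = 0
    age_mean_sd_patients: tuple[float, float] = (27.9, 8.3)
    age_mean_sd_controls: tuple[float, float] = (29.1, 7.5)
    rng_seed: int = 20100614

    def __post_init__(self):
        if self.n_patients + self.n_controls < 1:
            raise ValueError("cohort must contain at least one subject")
        for name in ("fc_coupling_controls", "fc_coupling_patients",
                     "reho_local_weight_controls", "reho_local_weight_patients"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_motion_outliers > self.n_patients:
            raise ValueError("more motion outliers than patients")
        if self.n_timepoints_acquired < 10:
            raise ValueError("need at least 10 acquired timepoints")

    def brain_mask(self) -> BrainMask:
        return default_brain_mask(self.grid)

    def roi_voxels(self, rois) -> np.ndarray:
        """(n, 3) in-mask voxel indices of the union of the given spheres."""
        mask = self.brain_mask().data
        union = np.zeros(self.grid.dims, dtype=bool)
        for roi in rois:
            sphere = sphere_mask(self.grid, roi.center_mm, roi.radius_mm)
            if not (sphere & mask).any():
                raise ValueError(f"ROI at {roi.center_mm} lies outside the brain mask")
            union |= sphere
        return np.argwhere(union & mask)


@dataclass
class GroundTruth:
    """Implanted-effect locations and cohort labels for recovery tests."""

    fc_effect_voxels: np.ndarray  # (n, 3) int, decreased seed coupling in patients
    reho_effect_voxels: np.ndarray  # (n, 3) int, decreased local synchrony
    motion_outlier_ids: tuple[str, ...]
    groups: dict[str, str]  # subject id -> "patient" | "control"

    def to_json(self) -> str:
        return json.dumps(
            {
                "fc_effect_voxels": self.fc_effect_voxels.tolist(),
                "reho_effect_voxels": self.reho_effect_voxels.tolist(),
                "motion_outlier_ids": list(self.motion_outlier_ids),
                "groups": self.groups,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            fc_effect_voxels=np.asarray(d["fc_effect_voxels"], dtype=int).reshape(-1, 3),
            reho_effect_voxels=np.asarray(d["reho_effect_voxels"], dtype=int).reshape(-1, 3),
            motion_outlier_ids=tuple(d["motion_outlier_ids"]),
            groups=dict(d["groups"]),
        )


def band_limited_series(rng: np.random.Generator, n: int, tr_seconds: float,
                        band_hz: tuple[float, float]) -> np.ndarray:
    """Unit-variance series obtained by ideal band-passing white noise.

    Built with the same frequency mask as the preprocessing band-pass, which
    guarantees implanted structure survives filtering unchanged.
    """
    lo, hi = band_hz
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    keep[0] = False
    if not keep.any():
        raise ValueError(f"band {band_hz} contains no DFT bin for n={n}, TR={tr_seconds}")
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n)
    return out / out.std()


def _smooth_walk(rng: np.random.Generator, n: int, peak: float) -> np.ndarray:
    """Random walk smoothed with a short moving average, rescaled to |max| = peak."""
    walk = np.cumsum(rng.standard_normal(n + 8))
    kernel = np.ones(9) / 9.0
    walk = np.convolve(walk, kernel, mode="valid")[:n]
    walk -= walk[0]
    m = np.abs(walk).max()
    return walk * (peak / m) if m > 0 else walk


def _motion_trace(rng: np.random.Generator, n: int, outlier: bool) -> MotionTrace:
    # compliant subjects peak well below the 10 mm / 1 degree limits;
    # outliers violate one randomly chosen axis
    t_peaks = np.clip(np.abs(rng.normal(1.0, 0.6, 3)), 0.05, 5.0)
    r_peaks_deg = np.clip(np.abs(rng.normal(0.12, 0.08, 3)), 0.005, 0.6)
    if outlier:
        if rng.random() < 0.5:
            t_peaks[rng.integers(3)] = rng.uniform(11.0, 15.0)
        else:
            r_peaks_deg[rng.integers(3)] = rng.uniform(1.2, 1.8)
    trans = np.column_stack([_smooth_walk(rng, n, p) for p in t_peaks])
    rots = np.column_stack([_smooth_walk(rng, n, np.radians(p)) for p in r_peaks_deg])
    return MotionTrace(translations_mm=trans, rotations_rad=rots)


def generate_subject(
    spec: CohortSpec, group: str, rng: np.random.Generator, motion_outlier: bool = False
) -> tuple[Volume4D, MotionTrace]:
    """One subject's 4D volume and motion trace.

    Voxel series = drift + seed/DMN terms + ReHo-ROI terms + white noise;
    see the module docstring for the coupling scheme.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"group must be 'patient' or 'control', got {group!r}")
    grid = spec.grid
    mask = spec.brain_mask().data
    n = spec.n_timepoints_acquired
    tr = spec.tr_seconds

    c_group = spec.fc_coupling_patients if group == "patient" else spec.fc_coupling_controls
    w_group = (
        spec.reho_local_weight_patients if group == "patient" else spec.reho_local_weight_controls
    )
    c_max = max(spec.fc_coupling_patients, spec.fc_coupling_controls)

    dmn_signal = band_limited_series(rng, n, tr, spec.band_hz)

    data = rng.standard_normal(grid.dims + (n,)) * spec.noise_sd
    t_axis = np.arange(n, dtype=float)
    slopes = rng.normal(0.0, spec.drift_slope_sd, grid.dims)
    data += slopes[..., None] * (t_axis - t_axis.mean())

    seed_vox = sphere_mask(grid, spec.seed_center_mm, spec.seed_radius_mm) & mask
    if not seed_vox.any():
        raise ValueError("seed sphere lies outside the brain mask")
    data[seed_vox] += c_max * dmn_signal

    for roi in spec.dmn_rois:
        vox = sphere_mask(grid, roi.center_mm, roi.radius_mm) & mask
        if not vox.any():
            raise ValueError(f"DMN ROI at {roi.center_mm} lies outside the brain mask")
        c = float(np.clip(rng.normal(c_group, spec.fc_coupling_subject_sd), 0.0, c_max))
        node_signal = band_limited_series(rng, n, tr, spec.band_hz)
        data[vox] += c * dmn_signal + np.sqrt(c_max**2 - c**2) * node_signal

    for roi in spec.reho_effect_rois:
        vox = sphere_mask(grid, roi.center_mm, roi.radius_mm) & mask
        if not vox.any():
            raise ValueError(f"ReHo ROI at {roi.center_mm} lies outside the brain mask")
        w = float(np.clip(rng.normal(w_group, spec.reho_weight_subject_sd), 0.0, 1.0))
        data[vox] += w * band_limited_series(rng, n, tr, spec.band_hz)

    vol = Volume4D(grid=grid, data=data, tr_seconds=tr)
    trace = _motion_trace(rng, n, motion_outlier)
    return vol, trace


def _demographics_row(rng: np.random.Generator, sid: str, group: str, spec: CohortSpec) -> dict:
    mean, sd = (
        spec.age_mean_sd_patients if group == "patient" else spec.age_mean_sd_controls
    )
    age = float(np.clip(rng.normal(mean, sd), 14, 50))
    sex = "M" if rng.random() < 0.5 else "F"
    education = rng.choice(["low", "high_school", "college"], p=[0.095, 0.46, 0.445])
    return {
        "subject_id": sid,
        "group": group,
        "age": round(age, 1),
        "sex": sex,
        "education": str(education),
    }


def _cohort_plan(spec: CohortSpec):
    ids = [f"pat{i + 1:03d}" for i in range(spec.n_patients)] + [
        f"con{i + 1:03d}" for i in range(spec.n_controls)
    ]
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    root = np.random.SeedSequence(spec.rng_seed)
    outlier_rng = np.random.default_rng(root.spawn(1)[0])
    outlier_ids = set(
        np.array(ids[: spec.n_patients])[
            outlier_rng.choice(spec.n_patients, size=spec.n_motion_outliers, replace=False)
        ]
        if spec.n_motion_outliers
        else []
    )
    streams = root.spawn(1 + len(ids))[1:]
    return ids, groups, outlier_ids, streams


def _ground_truth(spec: CohortSpec, ids, groups, outlier_ids) -> GroundTruth:
    return GroundTruth(
        fc_effect_voxels=spec.roi_voxels(spec.dmn_rois),
        reho_effect_voxels=spec.roi_voxels(spec.reho_effect_rois),
        motion_outlier_ids=tuple(sorted(outlier_ids)),
        groups=dict(zip(ids, groups)),
    )


def simulate_cohort(spec: CohortSpec):
    """In-memory cohort: yields (manifest DataFrame, GroundTruth, subject iterator).

    The iterator produces ``(subject_id, group, Volume4D, MotionTrace)`` one
    subject at a time so a full cohort never has to be resident at once.
    """
    ids, groups, outlier_ids, streams = _cohort_plan(spec)
    substreams = [ss.spawn(2) for ss in streams]  # (demographics, data) per subject
    rows = []
    for sid, group, (demo_ss, _) in zip(ids, groups, substreams):
        rows.append(_demographics_row(np.random.default_rng(demo_ss), sid, group, spec))
    manifest = pd.DataFrame(rows)
    truth = _ground_truth(spec, ids, groups, outlier_ids)

    def subjects():
        for sid, group, (_, data_ss) in zip(ids, groups, substreams):
            rng = np.random.default_rng(data_ss)
            vol, trace = generate_subject(spec, group, rng, motion_outlier=sid in outlier_ids)
            yield sid, group, vol, trace

    return manifest, truth, subjects()


def generate_cohort(spec: CohortSpec, out_dir, overwrite: bool = False):
    """Write a full cohort to disk: per-subject NIfTI volumes and rp-style
    motion traces, a manifest TSV, and ground-truth JSON.

    Returns (manifest DataFrame, GroundTruth).
    """
    from .io import write_bold_nifti, write_motion_trace

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    manifest, truth, subjects = simulate_cohort(spec)
    for sid, _group, vol, trace in subjects:
        write_bold_nifti(vol, out / f"{sid}_bold.nii.gz")
        write_motion_trace(trace, out / f"rp_{sid}.txt")
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
    return manifest, truth


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """Spec with equal group parameters (no implanted difference) for
    type-I-error calibration runs."""
    base = spec or CohortSpec()
    return replace(
        base,
        fc_coupling_patients=base.fc_coupling_controls,
        reho_local_weight_patients=base.reho_local_weight_controls,
        **overrides,
    )
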