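"""Reusable validation experiments on synthetic cohorts.

Three studies back the package's claims about its own statistics:

* :func:`recovery_experiment` — can the full pipeline recover implanted
  group effects at the standard thresholds (voxelwise p < 0.001, cluster
  extent > 50) and in the right direction only?
* :func:`null_type_one` — is the voxelwise false-positive rate of the group
  t-map at its nominal level when the two groups are simulated identically?
* :func:`reho_null_expectation` — does the ReHo map reproduce the analytic
  null mean E[W] = 1/K for independent series?

All run in memory on desk-scale grids and are deterministic given their
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import group_stats, reho, seed_fc
from .core import BrainMask, ImageGrid, StatMap, Volume4D
from .preprocess import PreprocessConfig, preprocess_volume
from .synthetic import CohortSpec, SphereROI, null_spec, simulate_cohort

__all__ = [
    "RecoveryResult",
    "recovery_experiment",
    "null_type_one",
    "reho_null_expectation",
    "small_cohort_spec",
]


@dataclass
class RecoveryResult:
    fc_decrease_clusters: list = field(default_factory=list)
    fc_increase_clusters: list = field(default_factory=list)
    reho_decrease_clusters: list = field(default_factory=list)
    reho_increase_clusters: list = field(default_factory=list)
    fc_dice: float = 0.0
    reho_dice: float = 0.0
    fc_t_map: StatMap | None = None
    reho_t_map: StatMap | None = None
    n_patients_used: int = 0
    n_controls_used: int = 0


def _subject_maps(spec: CohortSpec, pre_cfg: PreprocessConfig,
                  seed_spec: seed_fc.SeedSpec, stages=("reho", "fc")):
    """Simulate, preprocess and map every subject; yields per-group map lists."""
    brain = spec.brain_mask()
    _manifest, truth, subjects = simulate_cohort(spec)
    maps: dict[str, dict[str, list[StatMap]]] = {
        "W": {"patient": [], "control": []},
        "z": {"patient": [], "control": []},
    }
    for _sid, group, vol, _trace in subjects:
        pre = preprocess_volume(vol, brain, pre_cfg)
        if "reho" in stages:
            maps["W"][group].append(reho.reho_map(pre, brain))
        if "fc" in stages:
            _r, z = seed_fc.fc_maps(pre, brain, seed_spec)
            maps["z"][group].append(z)
    return brain, truth, maps


def recovery_experiment(
    spec: CohortSpec | None = None,
    pre_cfg: PreprocessConfig | None = None,
    seed_spec: seed_fc.SeedSpec | None = None,
    p_thresh: float = group_stats.DEFAULT_P_THRESH,
    extent: int = group_stats.DEFAULT_EXTENT,
) -> RecoveryResult:
    """End-to-end effect recovery on a simulated cohort.

    Runs the full chain on the given (default) cohort spec and reports, per
    contrast, the significant clusters split by sign and the Dice overlap of
    the decreased clusters with the implanted ground-truth voxels.
    """
    spec = spec or CohortSpec()
    pre_cfg = pre_cfg or PreprocessConfig()
    seed_spec = seed_spec or seed_fc.SeedSpec(
        center_mm=spec.seed_center_mm, radius_mm=spec.seed_radius_mm
    )
    brain, truth, maps = _subject_maps(spec, pre_cfg, seed_spec)

    result = RecoveryResult(
        n_patients_used=len(maps["z"]["patient"]),
        n_controls_used=len(maps["z"]["control"]),
    )
    for kind, label, truth_vox in (
        ("z", "fc", truth.fc_effect_voxels),
        ("W", "reho", truth.reho_effect_voxels),
    ):
        t_map = group_stats.two_sample_t(maps[kind]["patient"], maps[kind]["control"])
        records = group_stats.threshold_clusters(
            t_map, p_thresh=p_thresh, extent=extent, sign="both"
        )
        dec = [r for r in records if r.sign == "decrease"]
        inc = [r for r in records if r.sign == "increase"]
        dice = group_stats.dice_overlap(dec, truth_vox, spec.grid.dims)
        setattr(result, f"{label}_decrease_clusters", dec)
        setattr(result, f"{label}_increase_clusters", inc)
        setattr(result, f"{label}_dice", dice)
        setattr(result, f"{label}_t_map", t_map)
    return result


def small_cohort_spec(rng_seed: int = 7, **overrides) -> CohortSpec:
    """Compact cohort for fast replicate studies: 14^3 grid, 80 timepoints,
    one small DMN node and one small ReHo sphere around a 6 mm seed."""
    grid = ImageGrid.isotropic((14, 14, 14), 3.0, origin_mm=(-21.0, -21.0, -21.0))
    base = CohortSpec(
        n_patients=10,
        n_controls=10,
        grid=grid,
        n_timepoints_acquired=80,
        seed_center_mm=(0.0, 0.0, 0.0),
        seed_radius_mm=6.0,
        dmn_rois=(SphereROI((0.0, 13.0, 0.0), 6.0),),
        reho_effect_rois=(SphereROI((0.0, -13.0, 0.0), 6.0),),
        rng_seed=rng_seed,
    )
    return replace(base, **overrides) if overrides else base


def null_type_one(
    n_replicates: int = 10,
    p_thresh: float = group_stats.DEFAULT_P_THRESH,
    extent: int = group_stats.DEFAULT_EXTENT,
    rng_seed: int = 11,
    spec: CohortSpec | None = None,
) -> dict:
    """Voxelwise type-I error of the two-sample t on null cohorts.

    Groups are simulated with identical parameters; smoothing is disabled so
    voxelwise tests are spatially independent and the aggregate hit count is
    binomial.  Returns the aggregated rate over all in-mask voxels and
    replicates, its binomial standard error, and the mean count of
    significant clusters per map at the standard cluster rule.
    """
    base = null_spec(spec or small_cohort_spec())
    pre_cfg = PreprocessConfig(fwhm_mm=0.0)
    seed_spec = seed_fc.SeedSpec(center_mm=base.seed_center_mm, radius_mm=base.seed_radius_mm)
    n_tests = 0
    n_hits = 0
    n_clusters = 0
    for rep in range(n_replicates):
        spec_rep = replace(base, rng_seed=rng_seed + rep)
        _brain, _truth, maps = _subject_maps(spec_rep, pre_cfg, seed_spec, stages=("fc",))
        t_map = group_stats.two_sample_t(maps["z"]["patient"], maps["z"]["control"])
        p_map = group_stats.t_to_p(t_map)
        n_tests += t_map.mask.n_inside
        n_hits += int((p_map.values < p_thresh).sum())
        n_clusters += len(
            group_stats.threshold_clusters(t_map, p_thresh=p_thresh, extent=extent)
        )
    rate = n_hits / n_tests
    se = np.sqrt(p_thresh * (1 - p_thresh) / n_tests)
    return {
        "n_tests": n_tests,
        "n_hits": n_hits,
        "rate": rate,
        "nominal": p_thresh,
        "binomial_se": float(se),
        "clusters_per_map": n_clusters / n_replicates,
    }


def reho_null_expectation(
    n_side: int = 26,
    n_timepoints: int = 135,
    neighborhood: int = 27,
    rng_seed: int = 13,
) -> dict:
    """Mean ReHo W over independent white-noise series vs the analytic 1/K.

    W is sampled on a stride-3 interior lattice so the sampled neighborhoods
    are disjoint and the values independent; the returned standard error is
    the empirical sd of those values over sqrt(count).
    """
    rng = np.random.default_rng(rng_seed)
    grid = ImageGrid.isotropic((n_side,) * 3, 3.0)
    vol = Volume4D(grid=grid, data=rng.standard_normal(grid.dims + (n_timepoints,)),
                   tr_seconds=3.0)
    mask = BrainMask(grid=grid, data=np.ones(grid.dims, dtype=bool))
    w_map = reho.reho_map(vol, mask, neighborhood)
    sl = slice(1, n_side - 1, 3)
    sample = w_map.data[sl, sl, sl].ravel()
    return {
        "mean_w": float(sample.mean()),
        "expected": 1.0 / neighborhood,
        "se": float(sample.std(ddof=1) / np.sqrt(sample.size)),
        "n_voxels": int(sample.size),
    }
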