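"""Voxelwise t statistics, p/z conversion, cluster thresholding, reports."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from rehofc.core import BrainMask, ImageGrid, StatMap
from rehofc.group_stats import (
    cluster_report,
    dice_overlap,
    one_sample_t,
    t_to_p,
    t_to_z,
    threshold_clusters,
    two_sample_t,
)


def _maps(grid, mask, subject_values):
    """One StatMap per subject; subject_values is (m, n_inside)."""
    out = []
    for vals in subject_values:
        data = np.zeros(grid.dims)
        data[mask.data] = vals
        out.append(StatMap(grid=grid, mask=mask, kind="z", data=data))
    return out


@pytest.fixture
def small(grid8, full_mask8):
    return grid8, full_mask8


class TestOneSampleT:
    def test_worked_example(self, small):
        grid, mask = small
        n_in = mask.n_inside
        vals = np.vstack([np.full(n_in, v) for v in (1.0, 2.0, 3.0)])
        t = one_sample_t(_maps(grid, mask, vals))
        # mean 2, sd 1, m=3 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        assert t.values[0] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert t.meta["df"] == 2

    def test_zero_mean_gives_zero_t(self, small, rng):
        grid, mask = small
        base = rng.standard_normal(mask.n_inside)
        t = one_sample_t(_maps(grid, mask, np.vstack([base, -base])))
        assert np.allclose(t.values, 0.0, atol=1e-12)

    def test_all_zero_voxel_flagged(self, small):
        grid, mask = small
        t = one_sample_t(_maps(grid, mask, np.zeros((3, mask.n_inside))))
        assert t.flags[mask.data].all()
        assert (t.values == 0).all()


class TestTwoSampleT:
    def test_identical_groups_give_zero(self, small, rng):
        grid, mask = small
        vals = rng.standard_normal((3, mask.n_inside))
        maps = _maps(grid, mask, vals)
        t = two_sample_t(maps, _maps(grid, mask, vals))
        assert np.allclose(t.values, 0.0, atol=1e-12)

    def test_antisymmetry_under_group_swap(self, small, rng):
        grid, mask = small
        a = _maps(grid, mask, rng.standard_normal((4, mask.n_inside)))
        b = _maps(grid, mask, rng.standard_normal((5, mask.n_inside)))
        t_ab = two_sample_t(a, b)
        t_ba = two_sample_t(b, a)
        assert np.allclose(t_ab.values, -t_ba.values, atol=1e-12)

    def test_pooled_variance_worked_example(self, small):
        grid, mask = small
        a = _maps(grid, mask, [np.full(mask.n_inside, v) for v in (1.0, 2.0, 3.0)])
        b = _maps(grid, mask, [np.full(mask.n_inside, v) for v in (2.0, 3.0, 4.0)])
        t = two_sample_t(a, b)
        # pooled s^2 = 1, se = sqrt(2/3) -> t = -1 / sqrt(2/3)
        assert t.values[0] == pytest.approx(-1.224744871, abs=1e-9)
        assert t.meta["df"] == 4

    def test_matches_textbook_pooled_t_on_random_data(self, small, rng):
        grid, mask = small
        A = rng.standard_normal((6, mask.n_inside))
        B = rng.standard_normal((8, mask.n_inside)) + 0.3
        t = two_sample_t(_maps(grid, mask, A), _maps(grid, mask, B))
        oracle = stats.ttest_ind(A, B, axis=0, equal_var=True).statistic
        assert np.allclose(t.values, oracle, atol=1e-10)


class TestTtoPZ:
    def _t_map(self, grid, mask, t_vals, df):
        data = np.zeros(grid.dims)
        data[mask.data] = np.resize(t_vals, mask.n_inside)
        return StatMap(grid=grid, mask=mask, kind="t", data=data, meta={"df": df})

    def test_t_zero(self, small):
        grid, mask = small
        tm = self._t_map(grid, mask, [0.0], df=10)
        assert np.allclose(t_to_p(tm).values, 1.0)
        assert (t_to_z(tm).values == 0).all()

    def test_two_tailed_p_matches_density_integration(self, small):
        """p at t = 1.2247, df = 4 against direct numeric integration of the
        Student density (independent of scipy.stats.t)."""
        grid, mask = small
        df = 4
        tm = self._t_map(grid, mask, [1.224744871], df=df)
        p = t_to_p(tm).values[0]

        def density(x):
            c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _err = integrate.quad(density, 1.224744871, np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-9)
        assert p == pytest.approx(0.2879, abs=2e-4)

    def test_p_monotone_in_abs_t(self, small):
        grid, mask = small
        ts = np.linspace(-5, 5, mask.n_inside)
        p = t_to_p(self._t_map(grid, mask, ts, df=12))
        order = np.argsort(np.abs(ts))
        assert (np.diff(p.values[order]) <= 1e-12).all()

    def test_z_sign_preserving_and_finite_for_large_t(self, small):
        grid, mask = small
        z = t_to_z(self._t_map(grid, mask, [-50.0, 50.0, -2.0, 2.0], df=30))
        vals = z.values[:4]
        assert np.isfinite(vals).all()
        assert vals[0] == pytest.approx(-vals[1])
        assert vals[2] < 0 < vals[3]
        # matched tail probability: P(T > 2) with df 30 equals P(Z > z)
        assert stats.norm.sf(vals[3]) == pytest.approx(stats.t.sf(2.0, 30), rel=1e-10)

    def test_invalid_df(self, small):
        grid, mask = small
        with pytest.raises(ValueError):
            t_to_p(self._t_map(grid, mask, [1.0], df=10), df=0)


def _blob_t_map(grid, mask, blobs, t_value=10.0):
    """t map with rectangular suprathreshold blobs given as index slices."""
    data = np.zeros(grid.dims)
    for sl, v in blobs:
        data[sl] = v if v is not None else t_value
    return StatMap(grid=grid, mask=mask, kind="t", data=data, meta={"df": 38})


class TestThresholdClusters:
    @pytest.fixture
    def grid20(self):
        g = ImageGrid.isotropic((20, 20, 20), 3.0)
        return g, BrainMask(grid=g, data=np.ones(g.dims, dtype=bool))

    def test_extent_rule_is_strict(self, grid20):
        grid, mask = grid20
        # 51-voxel blob (17 x 3 x 1) and 49-voxel blob (7 x 7 x 1), separated
        tm = _blob_t_map(grid, mask, [
            ((slice(0, 17), slice(0, 3), slice(0, 1)), 10.0),
            ((slice(0, 7), slice(10, 17), slice(5, 6)), 10.0),
        ])
        recs = threshold_clusters(tm)
        assert len(recs) == 1
        assert recs[0].cluster_size_voxels == 51
        assert recs[0].sign == "increase"

    def test_empty_when_nothing_suprathreshold(self, grid20):
        grid, mask = grid20
        tm = _blob_t_map(grid, mask, [])
        assert threshold_clusters(tm) == []

    def test_corner_touching_blobs_connectivity(self, grid20):
        grid, mask = grid20
        # two 30-voxel slabs (5x6x1) touching only at one cube corner
        tm = _blob_t_map(grid, mask, [
            ((slice(0, 5), slice(0, 6), slice(4, 5)), 10.0),
            ((slice(5, 10), slice(6, 12), slice(5, 6)), 10.0),
        ])
        rec26 = threshold_clusters(tm, connectivity=26)
        assert [r.cluster_size_voxels for r in rec26] == [60]
        rec6 = threshold_clusters(tm, connectivity=6)
        assert rec6 == []  # two 30-voxel components, both under the extent rule

    def test_signs_split_and_peak_is_max_abs_t(self, grid20):
        grid, mask = grid20
        tm = _blob_t_map(grid, mask, [
            ((slice(0, 6), slice(0, 6), slice(0, 2)), 8.0),
            ((slice(10, 16), slice(10, 16), slice(10, 12)), -8.0),
        ])
        tm.data[2, 2, 0] = 12.0  # the peak
        recs = threshold_clusters(tm)
        inc = [r for r in recs if r.sign == "increase"]
        dec = [r for r in recs if r.sign == "decrease"]
        assert len(inc) == len(dec) == 1
        assert inc[0].peak_t == pytest.approx(12.0)
        assert inc[0].peak_index == (2, 2, 0)
        assert dec[0].peak_t == pytest.approx(-8.0)
        assert threshold_clusters(tm, sign="decrease") == dec

    def test_monotone_in_extent_and_p(self, grid20, rng):
        """Raising the extent or lowering p never adds retained voxels."""
        grid, mask = grid20
        data = rng.standard_normal(grid.dims) * 2
        tm = StatMap(grid=grid, mask=mask, kind="t", data=data, meta={"df": 38})

        def retained(p_thresh, extent):
            recs = threshold_clusters(tm, p_thresh=p_thresh, extent=extent)
            return {(r.sign, tuple(v)) for r in recs for v in r.voxel_indices.tolist()}

        base = retained(0.01, 5)
        assert retained(0.01, 20) <= base
        assert retained(0.001, 5) <= base


class TestClusterReport:
    def _record(self, x, sign="decrease", size=60):
        from rehofc.group_stats import ClusterRecord

        return ClusterRecord(
            cluster_size_voxels=size, sign=sign, peak_t=4.1, peak_z=3.7,
            peak_mm=(x, -39.0, 48.0), peak_index=(0, 0, 0),
            voxel_indices=np.zeros((size, 3), dtype=int),
        )

    def test_hemisphere_from_x_sign(self):
        df = cluster_report([self._record(-57.0), self._record(33.0), self._record(0.0)])
        assert list(df["hemisphere"]) == ["L", "R", "midline"]

    def test_sorted_by_size_descending(self):
        df = cluster_report([self._record(1.0, size=55), self._record(2.0, size=200)])
        assert list(df["cluster_size"]) == [200, 55]

    def test_empty_gives_header_only(self):
        df = cluster_report([])
        assert len(df) == 0
        assert "peak_t" in df.columns and "hemisphere" in df.columns


class TestDiceOverlap:
    def test_perfect_and_none(self, grid8):
        from rehofc.group_stats import ClusterRecord

        vox = np.argwhere(np.arange(8)[:, None, None] < 2)  # slab of 128 voxels
        rec = ClusterRecord(cluster_size_voxels=len(vox), sign="decrease", peak_t=-5,
                            peak_z=-4, peak_mm=(0, 0, 0), peak_index=(0, 0, 0),
                            voxel_indices=vox)
        assert dice_overlap([rec], vox, (8, 8, 8)) == pytest.approx(1.0)
        far = np.array([[7, 7, 7]])
        assert dice_overlap([rec], far, (8, 8, 8)) == pytest.approx(0.0)
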