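"""Preprocessing chain: discard, motion QC, smoothing, detrend, band-pass."""

import numpy as np
import pytest

from rehofc.core import BrainMask, ImageGrid, MotionTrace, Volume4D
from rehofc.preprocess import (
    FWHM_TO_SIGMA,
    PreprocessConfig,
    bandpass_ideal,
    detrend_linear,
    discard_initial,
    gaussian_smooth,
    qc_motion,
)


def _vol(grid, data, tr=3.0):
    return Volume4D(grid=grid, data=data, tr_seconds=tr)


class TestDiscardInitial:
    def test_140_minus_5_is_135(self, grid8, rng):
        vol = _vol(grid8, rng.standard_normal(grid8.dims + (140,)))
        out = discard_initial(vol, 5)
        assert out.n_timepoints == 135
        assert np.array_equal(out.data, vol.data[..., 5:])

    def test_zero_discard_is_identity(self, noise_vol8):
        assert np.array_equal(discard_initial(noise_vol8, 0).data, noise_vol8.data)

    def test_discarding_everything_fails(self, grid8, rng):
        vol = _vol(grid8, rng.standard_normal(grid8.dims + (5,)))
        with pytest.raises(ValueError):
            discard_initial(vol, 5)


class TestMotionQC:
    cfg = PreprocessConfig()

    def _trace(self, trans=0.0, rot_rad=0.0, n=20):
        t = np.zeros((n, 3))
        r = np.zeros((n, 3))
        t[n // 2, 0] = trans
        r[n // 2, 1] = rot_rad
        return MotionTrace(translations_mm=t, rotations_rad=r)

    def test_zero_trace_passes(self):
        v = qc_motion(self._trace(), self.cfg)
        assert v.passed and v.max_translation_mm == 0.0

    def test_translation_over_1cm_fails(self):
        v = qc_motion(self._trace(trans=12.0), self.cfg)
        assert not v.passed
        assert v.max_translation_mm == pytest.approx(12.0)
        assert "translation" in v.reasons[0]

    def test_rotation_just_over_1deg_fails(self):
        # 0.0175 rad = 1.0027 deg, past the 1 degree limit
        v = qc_motion(self._trace(rot_rad=0.0175), self.cfg)
        assert not v.passed
        assert v.max_rotation_deg == pytest.approx(1.0026761, abs=1e-5)

    def test_just_under_limits_passes(self):
        v = qc_motion(self._trace(trans=9.99, rot_rad=np.radians(0.99)), self.cfg)
        assert v.passed

    def test_empty_trace_rejected(self):
        trace = MotionTrace(translations_mm=np.zeros((0, 3)), rotations_rad=np.zeros((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            qc_motion(trace, self.cfg)


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, noise_vol8, full_mask8):
        out = gaussian_smooth(noise_vol8, 0.0, full_mask8)
        assert np.array_equal(out.data, noise_vol8.data)

    def test_constant_preserved(self, grid8, full_mask8):
        vol = _vol(grid8, np.full(grid8.dims + (3,), 7.0))
        out = gaussian_smooth(vol, 8.0, full_mask8)
        assert np.allclose(out.data, 7.0, atol=1e-6)

    def test_impulse_matches_direct_convolution(self):
        """Response to a unit impulse equals the brute-force separable
        sampled-Gaussian convolution (independent kernel construction).
        The probed block stays interior, where the in-mask renormalization
        is exactly 1 and the raw kernel must be recovered."""
        c = 11
        grid = ImageGrid.isotropic((23, 23, 23), 3.0)
        mask = BrainMask(grid=grid, data=np.ones(grid.dims, dtype=bool))
        data = np.zeros(grid.dims + (1,))
        data[c, c, c, 0] = 1.0
        out = gaussian_smooth(_vol(grid, data), 8.0, mask)

        sigma_vox = 8.0 * FWHM_TO_SIGMA / 3.0
        radius = int(4.0 * sigma_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (x / sigma_vox) ** 2)
        w /= w.sum()
        expected = np.einsum("i,j,k->ijk", w, w, w)  # separable 3D kernel
        sl = slice(c - radius, c + radius + 1)
        assert np.allclose(out.data[sl, sl, sl, 0], expected, atol=1e-9)

    def test_out_of_mask_voxels_never_leak_in(self, grid8, rng):
        inside = np.zeros(grid8.dims, dtype=bool)
        inside[2:6, 2:6, 2:6] = True
        mask = BrainMask(grid=grid8, data=inside)
        data = rng.standard_normal(grid8.dims + (2,))
        poisoned = data.copy()
        poisoned[~inside] = 1e6
        a = gaussian_smooth(_vol(grid8, data), 8.0, mask)
        b = gaussian_smooth(_vol(grid8, poisoned), 8.0, mask)
        assert np.allclose(a.data[inside], b.data[inside], atol=1e-6)

    def test_negative_fwhm_rejected(self, noise_vol8, full_mask8):
        with pytest.raises(ValueError):
            gaussian_smooth(noise_vol8, -1.0, full_mask8)


class TestDetrendLinear:
    def test_exact_line_removed(self, grid8):
        t = np.arange(30, dtype=float)
        data = np.broadcast_to(2.0 + 3.0 * t, grid8.dims + (30,)).copy()
        out = detrend_linear(_vol(grid8, data))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_projection_invariance(self, noise_vol8):
        """Adding any line to a series leaves the detrended output unchanged."""
        t = np.arange(noise_vol8.n_timepoints, dtype=float)
        shifted = noise_vol8.copy_with(noise_vol8.data + (5.0 - 0.7 * t))
        a = detrend_linear(noise_vol8)
        b = detrend_linear(shifted)
        assert np.allclose(a.data, b.data, atol=1e-9)

    def test_matches_normal_equations(self, grid8):
        """Residuals of [1, 2, 4] equal an independent normal-equations solve."""
        series = np.array([1.0, 2.0, 4.0])
        data = np.broadcast_to(series, grid8.dims + (3,)).copy()
        out = detrend_linear(_vol(grid8, data))
        # oracle: X = [1, t], beta = (X'X)^-1 X'y, residual = y - X beta
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        beta = np.linalg.solve(X.T @ X, X.T @ series)
        resid = series - X @ beta
        assert np.allclose(out.data[0, 0, 0], resid, atol=1e-12)
        assert out.data[0, 0, 0].sum() == pytest.approx(0.0, abs=1e-12)


class TestBandpassIdeal:
    n, tr = 135, 3.0

    def _sine(self, grid, freq):
        t = np.arange(self.n) * self.tr
        series = np.sin(2 * np.pi * freq * t)
        return _vol(grid, np.broadcast_to(series, grid.dims + (self.n,)).copy(), self.tr)

    def test_passband_preserved(self, grid8):
        vol = self._sine(grid8, 0.05)
        out = bandpass_ideal(vol, (0.01, 0.08))
        r = np.corrcoef(out.data[0, 0, 0], vol.data[0, 0, 0])[0, 1]
        assert r > 0.99

    def test_stopband_rejected(self, grid8):
        vol = self._sine(grid8, 0.12)
        out = bandpass_ideal(vol, (0.01, 0.08))
        assert out.data[0, 0, 0].var() < 0.01 * vol.data[0, 0, 0].var()

    def test_idempotent(self, noise_vol8):
        once = bandpass_ideal(noise_vol8, (0.01, 0.08))
        twice = bandpass_ideal(once, (0.01, 0.08))
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_orthogonal_to_out_of_band_frequency(self, grid8, rng):
        vol = _vol(grid8, rng.standard_normal(grid8.dims + (self.n,)), self.tr)
        out = bandpass_ideal(vol, (0.01, 0.08))
        # exact DFT frequency outside the band: k = 45 -> 45/(135*3) = 0.111 Hz
        t = np.arange(self.n)
        probe = np.cos(2 * np.pi * 45 * t / self.n)
        inner = np.abs(out.data.reshape(-1, self.n) @ probe)
        norms = np.linalg.norm(out.data.reshape(-1, self.n), axis=1) * np.linalg.norm(probe)
        assert (inner < 1e-6 * norms).all()

    def test_mean_removed(self, noise_vol8):
        out = bandpass_ideal(noise_vol8.copy_with(noise_vol8.data + 100.0), (0.01, 0.08))
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-9)

    def test_band_above_nyquist_rejected(self, noise_vol8):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_ideal(noise_vol8, (0.01, 0.2))  # Nyquist at TR 3 is 0.1667

    def test_reversed_band_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(band_hz=(0.08, 0.01))
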