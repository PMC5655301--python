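"""Per-subject preprocessing: initial-volume discard, motion QC, spatial
smoothing, linear detrend, ideal band-pass.

The default stage order (smooth -> detrend -> bandpass) mirrors the classic
SPM + REST resting-state chain: the first acquired volumes are discarded while
the scanner reaches steady state, subjects moving more than 10 mm / 1 degree
are excluded, volumes are smoothed with an 8 mm FWHM Gaussian, and each
voxel's series is detrended and band-passed to 0.01-0.08 Hz.  A
``conventional`` order flag defers smoothing until after ReHo (see
:mod:`rehofc.reho`).

All spatial operations are mask-respecting: voxels outside the brain mask
never influence in-mask values (the Gaussian kernel is renormalized over
in-mask support, so a constant in-mask image stays constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BrainMask, MotionTrace, Volume4D

__all__ = [
    "PreprocessConfig",
    "QCVerdict",
    "discard_initial",
    "qc_motion",
    "gaussian_smooth",
    "detrend_linear",
    "bandpass_ideal",
    "preprocess_volume",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    max_translation_mm / max_rotation_deg are the head-motion exclusion
    limits (1 cm and 1 degree by default, evaluated per axis); fwhm_mm the
    smoothing kernel width; band_hz the retained frequency band.
    """

    n_discard: int = 5
    max_translation_mm: float = 10.0
    max_rotation_deg: float = 1.0
    fwhm_mm: float = 8.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    stage_order: str = "paper"  # "paper": smooth before ReHo; "conventional": after

    def __post_init__(self):
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.band_hz}: need 0 < low < high")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.stage_order not in ("paper", "conventional"):
            raise ValueError("stage_order must be 'paper' or 'conventional'")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    max_translation_mm: float
    max_rotation_deg: float
    reasons: tuple[str, ...] = field(default_factory=tuple)


def discard_initial(vol: Volume4D, n_discard: int = 5) -> Volume4D:
    """Drop the first *n_discard* timepoints (scanner steady-state settle)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= vol.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_timepoints} timepoints"
        )
    if n_discard == 0:
        return vol.copy_with(vol.data.copy())
    return vol.copy_with(vol.data[..., n_discard:].copy())


def qc_motion(trace: MotionTrace, cfg: PreprocessConfig) -> QCVerdict:
    """Per-axis head-motion check: fail iff any |translation| >= limit (mm)
    or any |rotation| >= limit (degrees)."""
    if trace.n_timepoints == 0:
        raise ValueError("empty motion trace")
    max_t = float(np.abs(trace.translations_mm).max())
    max_r = float(np.abs(trace.rotations_deg).max())
    reasons = []
    if max_t >= cfg.max_translation_mm:
        reasons.append(f"translation {max_t:.2f} mm >= {cfg.max_translation_mm} mm")
    if max_r >= cfg.max_rotation_deg:
        reasons.append(f"rotation {max_r:.3f} deg >= {cfg.max_rotation_deg} deg")
    return QCVerdict(
        passed=not reasons,
        max_translation_mm=max_t,
        max_rotation_deg=max_r,
        reasons=tuple(reasons),
    )


def _smooth3(img: np.ndarray, sigma_vox, truncate: float = 4.0) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=sigma_vox, mode="constant", cval=0.0, truncate=truncate)


def gaussian_smooth(vol: Volume4D, fwhm_mm: float, mask: BrainMask) -> Volume4D:
    """Isotropic Gaussian smoothing in mm, renormalized over in-mask support.

    sigma per axis = fwhm / (2*sqrt(2*ln 2)) / voxel_size.  Each timepoint is
    convolved with the sampled-Gaussian kernel; dividing by the smoothed mask
    keeps a constant in-mask image constant and stops out-of-mask zeros from
    bleeding in at the brain edge.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    mask.check_same_grid(vol)
    if fwhm_mm == 0:
        return vol.copy_with(vol.data.copy())
    sigma_vox = tuple(fwhm_mm * FWHM_TO_SIGMA / vs for vs in vol.grid.voxel_size_mm)
    m = mask.data.astype(float)
    norm = _smooth3(m, sigma_vox)
    out = np.zeros_like(vol.data)
    inside = mask.data
    for t in range(vol.n_timepoints):
        sm = _smooth3(np.where(inside, vol.data[..., t], 0.0), sigma_vox)
        out[..., t][inside] = sm[inside] / norm[inside]
    return vol.copy_with(out)


def detrend_linear(vol: Volume4D, mask: BrainMask | None = None) -> Volume4D:
    """Remove each voxel's least-squares line (intercept + slope).

    Output series have zero mean and zero linear trend; correlations and
    rank statistics downstream are invariant to the mean removal.
    """
    n = vol.n_timepoints
    if n < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    data = vol.data
    mean = data.mean(axis=-1, keepdims=True)
    slope = (data * tc).sum(axis=-1, keepdims=True) / (tc**2).sum()
    out = data - mean - slope * tc
    if mask is not None:
        mask.check_same_grid(vol)
        out = np.where(mask.data[..., None], out, 0.0)
    return vol.copy_with(out)


def bandpass_frequencies(n: int, tr_seconds: float) -> np.ndarray:
    """Frequency grid f_k = k / (n * TR) for the one-sided DFT, k = 0..n//2."""
    return np.fft.rfftfreq(n, d=tr_seconds)


def bandpass_ideal(
    vol: Volume4D,
    band_hz: tuple[float, float] = (0.01, 0.08),
    mask: BrainMask | None = None,
) -> Volume4D:
    """Ideal (frequency-mask) band-pass along time.

    DFT coefficients with frequency strictly below band low or strictly above
    band high are zeroed, as is the zero-frequency (mean) term; the filter is
    exactly idempotent.  Band high must be below the Nyquist 1/(2*TR).
    """
    lo, hi = band_hz
    nyq = 1.0 / (2.0 * vol.tr_seconds)
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band_hz}")
    if hi >= nyq:
        raise ValueError(f"band high {hi} Hz >= Nyquist {nyq:.4f} Hz")
    n = vol.n_timepoints
    freqs = bandpass_frequencies(n, vol.tr_seconds)
    keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    keep[0] = False
    spec = np.fft.rfft(vol.data, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    if mask is not None:
        mask.check_same_grid(vol)
        out = np.where(mask.data[..., None], out, 0.0)
    return vol.copy_with(out)


def preprocess_volume(
    vol: Volume4D, mask: BrainMask, cfg: PreprocessConfig
) -> Volume4D:
    """Full per-subject chain: discard -> [smooth] -> detrend -> bandpass.

    Under ``stage_order='conventional'`` smoothing is skipped here (ReHo runs
    on unsmoothed data and the W map is smoothed afterwards instead).
    """
    out = discard_initial(vol, cfg.n_discard)
    if cfg.stage_order == "paper":
        out = gaussian_smooth(out, cfg.fwhm_mm, mask)
    out = detrend_linear(out, mask)
    out = bandpass_ideal(out, cfg.band_hz, mask)
    return out
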