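"""End-to-end correction experiments and quantitative metrics.

Everything here reports enhancement at *equal delivered power*: after
binarization the pupil amplitude is scaled by sqrt(1/power_ratio) so the
power on the sample matches the blank-mask acquisition, exactly as the
instrument raises the laser power into the DMD.  Enhancement is the ratio of
peak two-photon signals at the target (background excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation, gaussian_filter, median_filter
from scipy.stats import linregress

from .config import OpticalConfig
from .media import ScatteringMedium
from .optics import (pattern_signals, propagate_to_focus, transfer_vector,
                     two_photon_signal, _through_screens, _apply_transfer,
                     _fftc, pupil_field)
from .patterns import (BinaryMask, GrayscaleMask, PatternSet, binarize_mask,
                       blank_mask, generate_random_patterns,
                       normalize_delivered_power, power_ratio)
from .recon import (CorrectionResult, ReconConfig, compute_correction_mask,
                    fista_solve, focus_initial_guess)

__all__ = ["MeasurementSet", "NoiseModel", "PSFMetrics", "EALFit",
           "acquire_measurements", "enhancement_fold", "peak_signal",
           "enhancement_from_transfer", "psf_metrics", "eal_fit",
           "run_measurement_sweep", "run_ratio_sweep", "postprocess_image",
           "memory_effect_correlation", "psf_stack"]


@dataclass(frozen=True)
class NoiseModel:
    """Optional detection noise: Poisson shot noise at ``photons_per_unit``
    photons per signal unit, Gaussian read noise, and a PMT saturation clip."""

    photons_per_unit: float | None = None
    read_std: float = 0.0
    clip_level: float | None = None

    def apply(self, signals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(signals, dtype=float)
        if self.photons_per_unit:
            out = rng.poisson(out * self.photons_per_unit) / self.photons_per_unit
        if self.read_std > 0:
            out = out + rng.normal(0.0, self.read_std, out.shape)
        if self.clip_level is not None:
            out = np.minimum(out, self.clip_level)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class MeasurementSet:
    """Fluorescence intensities aligned to a pattern set (acquisition order)."""

    intensities: np.ndarray
    dwell_time: float = 0.5e-3  # seconds per pattern
    noise: NoiseModel | None = None
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.intensities, dtype=float).ravel()
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "intensities", v)

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def total_acquisition_time(self) -> float:
        """Simulated acquisition span in seconds (patterns x dwell)."""
        return len(self) * self.dwell_time

    def subset(self, n: int) -> "MeasurementSet":
        return MeasurementSet(self.intensities[:n], self.dwell_time,
                              self.noise, self.seed)


def acquire_measurements(patterns: PatternSet, medium: ScatteringMedium,
                         target_or_phantom, cfg: OpticalConfig,
                         noise: NoiseModel | None = None,
                         dwell_time: float = 0.5e-3, amplitude: float = 1.0,
                         depth: float = 0.0, seed: int = 0) -> MeasurementSet:
    """One fluorescence intensity per projected pattern.

    A point target (``(x, y, z)`` tuple) uses the transfer-vector fast path
    ``|A u|^4``; an extended phantom falls back to full propagation per
    pattern.  Deterministic given the seed (noise only).
    """
    amp = amplitude * medium.amplitude_factor(depth)
    if isinstance(target_or_phantom, tuple):
        u = transfer_vector(medium, cfg, target_or_phantom)
        signals = pattern_signals(patterns, u, amplitude=amp)
    else:
        signals = np.array([
            two_photon_signal(patterns.mask(i), medium, target_or_phantom,
                              cfg, amplitude=amp)
            for i in range(len(patterns))])
    if noise is not None:
        signals = noise.apply(signals, np.random.default_rng(seed))
    return MeasurementSet(signals, dwell_time, noise, seed)


# ---------------------------------------------------------------------------
# enhancement

def enhancement_fold(corrected_signal: float, uncorrected_signal: float) -> float:
    """Corrected-to-uncorrected peak-signal ratio at equal delivered power."""
    if uncorrected_signal <= 0:
        raise ValueError("undefined enhancement: uncorrected signal is zero")
    return float(corrected_signal) / float(uncorrected_signal)


def peak_signal(mask: BinaryMask, u: np.ndarray, equal_power: bool = True) -> float:
    """Fast-path two-photon peak signal of a binary mask at the target.

    With ``equal_power`` the delivered power is equalised to the blank mask,
    so the signal picks up a factor (1/power_ratio)^2.
    """
    amp = normalize_delivered_power(mask) if equal_power else 1.0
    fld = u.ravel()[mask.values.ravel()].sum()
    return float(np.abs(amp * fld) ** 4)


def enhancement_from_transfer(mask: BinaryMask, u: np.ndarray) -> float:
    """Enhancement of ``mask`` over the blank mask at equal delivered power."""
    blank_field = u.ravel().sum()
    blank_signal = float(np.abs(blank_field) ** 4)
    return enhancement_fold(peak_signal(mask, u), blank_signal)


# ---------------------------------------------------------------------------
# PSF metrology

@dataclass(frozen=True)
class PSFMetrics:
    fwhm_x: float
    fwhm_y: float
    fwhm_z: float
    contrast: float
    peak: float
    peak_index: tuple[int, int, int]


def _fwhm_1d(profile: np.ndarray, pitch: float, peak_idx: int) -> float:
    """FWHM by cubic interpolation of the half-maximum crossings."""
    v = np.asarray(profile, dtype=float)
    half = v[peak_idx] / 2.0
    idx = np.arange(len(v))
    spline = CubicSpline(idx, v - half)
    roots = spline.roots(extrapolate=False)
    left = roots[roots < peak_idx]
    right = roots[roots > peak_idx]
    if len(left) == 0 or len(right) == 0:
        raise ValueError("unresolved: no half-maximum crossing in the profile")
    return float((right.min() - left.max()) * pitch)


def psf_metrics(stack: np.ndarray, pitch=(1.0, 1.0, 1.0),
                peak_hint: tuple[int, int, int] | None = None) -> PSFMetrics:
    """FWHM and contrast of a dominant peak in a (z, y, x) stack.

    ``pitch = (dz, dy, dx)`` in µm.  FWHMs come from 1-D profiles through
    the peak with cubic interpolation at half maximum; contrast is
    (peak - median background) / median background over an annulus 5-10
    lateral FWHM from the peak in the peak's z-slice.  A 2-D image is
    treated as a single-slice stack (``fwhm_z = nan``).
    """
    s = np.asarray(stack, dtype=float)
    if s.ndim == 2:
        s = s[None]
    dz, dy, dx = pitch
    if peak_hint is not None:
        pz, py, px = peak_hint
    else:
        pz, py, px = np.unravel_index(int(np.argmax(s)), s.shape)
    peak = float(s[pz, py, px])
    if peak <= 0 or np.ptp(s) == 0:
        raise ValueError("unresolved: stack has no dominant peak")
    fwhm_x = _fwhm_1d(s[pz, py, :], dx, px)
    fwhm_y = _fwhm_1d(s[pz, :, px], dy, py)
    fwhm_z = _fwhm_1d(s[:, py, px], dz, pz) if s.shape[0] >= 5 else float("nan")

    plane = s[pz]
    yy, xx = np.indices(plane.shape)
    r_um = np.sqrt(((yy - py) * dy) ** 2 + ((xx - px) * dx) ** 2)
    annulus = (r_um >= 5.0 * fwhm_x) & (r_um <= 10.0 * fwhm_x)
    if not annulus.any():
        annulus = r_um >= 5.0 * fwhm_x
    if annulus.any():
        bg = float(np.median(plane[annulus]))
        contrast = (peak - bg) / bg if bg > 0 else float("inf")
    else:
        warnings.warn("no background annulus available; contrast undefined",
                      RuntimeWarning, stacklevel=2)
        contrast = float("nan")
    return PSFMetrics(fwhm_x, fwhm_y, fwhm_z, contrast, peak, (pz, py, px))


def psf_stack(mask, medium: ScatteringMedium, cfg: OpticalConfig,
              z_range: np.ndarray, half_size: int = 32,
              equal_power: bool = True) -> np.ndarray:
    """Two-photon intensity (|E|^4) stack around the focus for PSF metrology."""
    if isinstance(mask, BinaryMask) and equal_power:
        amp = normalize_delivered_power(mask)
    else:
        amp = 1.0
    b = _through_screens(pupil_field(mask, cfg, amp), medium, cfg)
    n2 = cfg.field_grid // 2
    sl = slice(n2 - half_size, n2 + half_size + 1)
    out = []
    for z in z_range:
        e = _fftc(_apply_transfer(b, cfg, float(z)))
        out.append((np.abs(e[sl, sl]) ** 2) ** 2)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# effective attenuation length

@dataclass(frozen=True)
class EALFit:
    """Exponential-decay fit of peak signal vs depth.

    Two-photon convention: excitation attenuates as exp(-z/EAL), so the
    signal decays as exp(-2 z/EAL) and EAL = -2/slope of ln(signal) vs z.
    """

    eal: float
    slope: float
    intercept: float
    r_value: float
    segments: tuple = ()


def eal_fit(depths, signals, breakpoint: float | None = None) -> EALFit:
    """Least-squares EAL fit; optional piecewise fit at a stated breakpoint."""
    z = np.asarray(depths, dtype=float)
    s = np.asarray(signals, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least three depth points")
    if (s <= 0).any():
        raise ValueError("signals must be positive for a log fit")
    res = linregress(z, np.log(s))
    if res.slope >= 0:
        warnings.warn("signals do not decay with depth; EAL reported as "
                      "infinity", RuntimeWarning, stacklevel=2)
        eal = float("inf")
    else:
        eal = -2.0 / res.slope
    segments = ()
    if breakpoint is not None:
        segs = []
        for sel in (z <= breakpoint, z >= breakpoint):
            if sel.sum() >= 3:
                sub = linregress(z[sel], np.log(s[sel]))
                segs.append((float(z[sel].min()), float(z[sel].max()),
                             -2.0 / sub.slope if sub.slope < 0 else float("inf")))
        segments = tuple(segs)
    return EALFit(eal, float(res.slope), float(res.intercept),
                  float(res.rvalue), segments)


# ---------------------------------------------------------------------------
# sweeps

def run_measurement_sweep(medium: ScatteringMedium, target, counts,
                          cfg: OpticalConfig,
                          recon_cfg: ReconConfig | None = None,
                          sparsity: float = 0.4, power_ratio_: float = 0.30,
                          master_seed: int = 0,
                          noise: NoiseModel | None = None) -> pd.DataFrame:
    """Enhancement vs measurement count.

    One master pattern set of ``max(counts)`` patterns is generated and each
    count uses its prefix, so the sweep is nested rather than resampled.
    """
    counts = sorted(int(c) for c in counts)
    master = generate_random_patterns(counts[-1], cfg.superpixel_grid,
                                      sparsity, master_seed,
                                      cfg.superpixel_size)
    u = transfer_vector(medium, cfg, target)
    ms = acquire_measurements(master, medium, target, cfg, noise=noise,
                              seed=master_seed)
    rows = []
    for c in counts:
        res = compute_correction_mask(master.subset(c), ms.subset(c),
                                      recon_cfg, power_ratio_)
        rows.append({"count": c,
                     "enhancement": enhancement_from_transfer(res.binary, u),
                     "iterations": res.diagnostics.iterations,
                     "seed": master_seed})
    return pd.DataFrame(rows)


def run_ratio_sweep(medium: ScatteringMedium, target,
                    grayscale_mask: GrayscaleMask, ratios,
                    cfg: OpticalConfig, compute_psf: bool = False,
                    z_range: np.ndarray | None = None) -> pd.DataFrame:
    """Metrics vs binarization threshold (output-to-input power ratio).

    All rows are evaluated at equal delivered power.  With ``compute_psf``
    the lateral/axial FWHM and contrast of the corrected focus are measured
    from a simulated |E|^4 stack around the target.
    """
    u = transfer_vector(medium, cfg, target)
    rows = []
    for r in ratios:
        binary = binarize_mask(grayscale_mask, r, cfg.superpixel_size)
        row = {"ratio": float(r),
               "enhancement": enhancement_from_transfer(binary, u),
               "on_count": binary.on_count}
        if compute_psf:
            zr = z_range if z_range is not None else \
                np.linspace(-4.0, 4.0, 17) + target[2]
            stack = psf_stack(binary, medium, cfg, zr)
            pitch = (float(zr[1] - zr[0]), cfg.focal_pixel_pitch,
                     cfg.focal_pixel_pitch)
            try:
                m = psf_metrics(stack, pitch)
                row.update(fwhm_x=m.fwhm_x, fwhm_z=m.fwhm_z,
                           contrast=m.contrast)
            except ValueError:
                row.update(fwhm_x=np.nan, fwhm_z=np.nan, contrast=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# memory effect

def memory_effect_correlation(medium: ScatteringMedium, cfg: OpticalConfig,
                              shifts, mask=None) -> np.ndarray:
    """Correlation of the shift-compensated focal speckle vs scan shift.

    For each lateral shift d (µm) the blank-pupil (or given mask) focal
    intensity is computed with the corresponding scan tilt, rolled back by d,
    and Pearson-correlated with the untilted pattern over the central half
    of the grid.  A screen at the pupil gives correlation 1 for every shift;
    a screen in the focal region decorrelates with |d|.
    """
    if mask is None:
        mask = blank_mask(cfg.superpixel_grid, cfg.superpixel_size)
    ref = propagate_to_focus(mask, medium, cfg).intensity
    n = cfg.field_grid
    c0, c1 = n // 4, 3 * n // 4
    out = []
    for d in shifts:
        # snap to the focal grid so the compensating roll is exact
        px = int(round(d / cfg.focal_pixel_pitch))
        i = propagate_to_focus(mask, medium, cfg,
                               tilt=(px * cfg.focal_pixel_pitch, 0.0)).intensity
        i = np.roll(i, -px, axis=1)
        a = i[c0:c1, c0:c1].ravel()
        bvec = ref[c0:c1, c0:c1].ravel()
        out.append(float(np.corrcoef(a, bvec)[0, 1]))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# digital image post-processing

def _notch(image: np.ndarray, freqs, radius: float) -> np.ndarray:
    f = np.fft.fftshift(np.fft.fft2(image))
    h, w = image.shape
    fy = (np.arange(h) - h // 2) / h
    fx = (np.arange(w) - w // 2) / w
    yy, xx = np.meshgrid(fy, fx, indexing="ij")
    keep = np.ones((h, w), dtype=bool)
    for (nfy, nfx) in freqs:
        for sy, sx in ((nfy, nfx), (-nfy, -nfx)):
            keep &= (yy - sy) ** 2 + (xx - sx) ** 2 > radius ** 2
    keep[h // 2, w // 2] = True  # never notch DC
    return np.real(np.fft.ifft2(np.fft.ifftshift(f * keep)))


def postprocess_image(image: np.ndarray, notch_freqs=None,
                      notch_radius: float = 0.01, median_size: int = 3,
                      unsharp_sigma: float = 10.0, labels=None,
                      border: int = 2) -> np.ndarray:
    """Denoise and flatten a corrected image.

    Frequency-domain notch at the given stripe frequencies (cycles/pixel),
    then a median filter, unsharp-mask background subtraction, and — when a
    subregion label image is supplied — median-ratio gain blending within a
    ``border``-pixel band on each side of every subregion boundary.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    out = img.copy()
    if notch_freqs:
        out = _notch(out, notch_freqs, notch_radius)
    if median_size and median_size > 1:
        out = median_filter(out, size=median_size)
    if unsharp_sigma:
        out = np.maximum(out - gaussian_filter(out, unsharp_sigma), 0.0)
    if labels is not None:
        out = _blend_borders(out, np.asarray(labels), border)
    return out


def _blend_borders(img: np.ndarray, labels: np.ndarray, border: int) -> np.ndarray:
    out = img.copy()
    ids = np.unique(labels)
    for i, a in enumerate(ids):
        for b_lab in ids[i + 1:]:
            ra, rb = labels == a, labels == b_lab
            band_a = ra & binary_dilation(rb, iterations=border)
            band_b = rb & binary_dilation(ra, iterations=border)
            if not band_a.any() or not band_b.any():
                continue
            ma, mb = np.median(img[band_a]), np.median(img[band_b])
            if ma <= 0 or mb <= 0:
                continue
            g = np.sqrt(mb / ma)
            out[band_a] = img[band_a] * g
            out[band_b] = img[band_b] / g
    return out
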