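"""Scattering media: random phase screens standing in for tissue.

A medium is a stack of thin phase-only screens.  A screen at a finite
``z_position`` (µm from the focal plane, positive toward the objective) lives
on the real-space field grid and is traversed by the converging scan cone, so
a lateral scan shifts the beam footprint across it — this is what produces
the finite, tens-of-µm optical memory effect.  A screen "at the pupil"
(``z_position=None``) multiplies the pupil field directly; it commutes with
the scan tilt ramp and therefore has an infinite memory effect, which makes
it the convenient choice for unit tests.

Attenuation with depth is modeled, when requested, by a single multiplicative
factor exp(-depth/EAL) on delivered power (so the two-photon signal decays as
exp(-2·depth/EAL)) — enough to exercise effective-attenuation-length fitting
without radiative transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import OpticalConfig

__all__ = ["PhaseScreen", "ScatteringMedium", "make_phase_screen",
           "make_pupil_screen", "identity_medium"]


@dataclass(frozen=True)
class PhaseScreen:
    """One thin phase screen.

    ``z_position`` is µm from the focal plane (``None`` = pupil-plane screen,
    in which case ``phase`` is on the pupil grid rather than the field grid).
    """

    phase: np.ndarray  # radians
    z_position: float | None
    correlation_length: float
    phase_std: float
    seed: int

    def __post_init__(self):
        ph = np.asarray(self.phase, dtype=float)
        if not np.isfinite(ph).all():
            raise ValueError("phase map must be finite")
        object.__setattr__(self, "phase", ph)

    @property
    def at_pupil(self) -> bool:
        return self.z_position is None


@dataclass(frozen=True)
class ScatteringMedium:
    """Stack of phase screens plus an optional bulk attenuation length."""

    screens: tuple[PhaseScreen, ...] = ()
    attenuation_eal: float | None = None  # µm; None = no attenuation

    def __post_init__(self):
        object.__setattr__(self, "screens", tuple(self.screens))
        if self.attenuation_eal is not None and self.attenuation_eal <= 0:
            raise ValueError("attenuation EAL must be positive")

    @property
    def is_identity(self) -> bool:
        return all(s.phase_std == 0 for s in self.screens)

    def amplitude_factor(self, depth: float) -> float:
        """Field-amplitude factor at imaging depth (power ∝ exp(-depth/EAL))."""
        if self.attenuation_eal is None or depth == 0:
            return 1.0
        return float(np.exp(-depth / (2.0 * self.attenuation_eal)))

    def ordered_screens(self) -> tuple[PhaseScreen, ...]:
        """Screens in traversal order: pupil screens first, then descending z."""
        pupil = [s for s in self.screens if s.at_pupil]
        rest = sorted((s for s in self.screens if not s.at_pupil),
                      key=lambda s: -s.z_position)
        return tuple(pupil + rest)


def _gaussian_random_field(shape: tuple[int, int], corr_px: float,
                           std: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian field with Gaussian autocorrelation, exact expected variance.

    White noise filtered with a Gaussian kernel of sigma = corr_px / 2 has
    autocorrelation exp(-r^2 / corr_px^2) (correlation length = 1/e radius);
    the filter's l2 norm is divided out so the pointwise variance is std^2 in
    expectation, independent of corr_px.
    """
    if std == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma = corr_px / 2.0
    smoothed = gaussian_filter(white, sigma=sigma, mode="wrap")
    # exact variance of the filtered field: product of the axis kernels' l2
    # norms squared (separable filter, periodic boundary)
    var = 1.0
    for n in shape:
        impulse = np.zeros(n)
        impulse[n // 2] = 1.0
        ir = gaussian_filter(impulse, sigma=sigma, mode="wrap")
        var *= float(np.sum(ir ** 2))
    return smoothed * (std / np.sqrt(var))


def make_phase_screen(cfg: OpticalConfig, correlation_length: float,
                      phase_std: float, z_position: float,
                      seed: int = 0) -> ScatteringMedium:
    """Single random screen at ``z_position`` µm from the focal plane.

    ``correlation_length`` is the physical 1/e correlation radius in µm on
    the field grid.  ``phase_std=0`` yields the identity (aberration-free)
    medium.  Deterministic given ``seed``.
    """
    pitch = cfg.focal_pixel_pitch
    corr_px = correlation_length / pitch
    if phase_std < 0:
        raise ValueError("phase_std must be non-negative")
    if corr_px < 2.0:
        raise ValueError("unresolvable screen: correlation_length below twice "
                         "the grid pitch")
    rng = np.random.default_rng(seed)
    n = cfg.field_grid
    phase = _gaussian_random_field((n, n), corr_px, phase_std, rng)
    screen = PhaseScreen(phase, float(z_position), correlation_length,
                         phase_std, seed)
    return ScatteringMedium((screen,))


def make_pupil_screen(cfg: OpticalConfig, correlation_length_px: float,
                      phase_std: float, seed: int = 0) -> ScatteringMedium:
    """Random screen applied in the pupil plane (infinite memory effect).

    ``correlation_length_px`` is the 1/e correlation radius in pupil samples.
    """
    if phase_std < 0:
        raise ValueError("phase_std must be non-negative")
    if correlation_length_px < 2.0:
        raise ValueError("unresolvable screen: correlation length below twice "
                         "the pupil sample pitch")
    rng = np.random.default_rng(seed)
    n = cfg.pupil_grid
    phase = _gaussian_random_field((n, n), correlation_length_px, phase_std, rng)
    screen = PhaseScreen(phase, None, correlation_length_px, phase_std, seed)
    return ScatteringMedium((screen,))


def identity_medium() -> ScatteringMedium:
    """Aberration-free medium."""
    return ScatteringMedium(())
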