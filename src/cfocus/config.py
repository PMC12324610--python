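"""Optical configuration of the virtual two-photon microscope.

All lengths are micrometres.  The pupil (Fourier) plane is the square DMD
aperture sampled at mirror-block resolution; the focal region is reached by a
single scaled Fourier transform, so the focal-plane sampling is fully
determined by the pupil sampling:

    dnu         = 2 * nu_half / pupil_grid        (pupil frequency pitch)
    focal_pitch = 1 / (field_grid * dnu)          (focal-plane sample pitch)
    fov         = 1 / dnu                         (unaliased focal extent)

The square aperture is inscribed in the NA circle (its diagonal subtends the
stated NA), so every superpixel carries a propagating plane wave and the
uniform-illumination power-ratio convention is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticalConfig"]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of the simulated microscope.

    Parameters
    ----------
    wavelength : excitation wavelength in µm (1.035 µm default).
    numerical_aperture : objective NA (bounds the pupil-square diagonal).
    medium_index : immersion/tissue refractive index (water, 1.33).
    pupil_grid : pupil samples per side across the DMD square (800 = the
        usable DMD region at mirror-block resolution).
    superpixel_size : pupil samples per superpixel side (8), so the
        superpixel grid is ``pupil_grid // superpixel_size`` per side.
    field_grid : FFT grid side for focal-region fields (power of two).
    scan_pixel_pitch : lateral scan step of the point-scanned image, µm.
    z_step : axial step between image planes, µm.
    """

    wavelength: float = 1.035
    numerical_aperture: float = 1.0
    medium_index: float = 1.33
    pupil_grid: int = 800
    superpixel_size: int = 8
    field_grid: int = 2048
    scan_pixel_pitch: float = 0.44
    z_step: float = 10.0

    def __post_init__(self):
        if min(self.wavelength, self.numerical_aperture, self.medium_index,
               self.scan_pixel_pitch, self.z_step) <= 0:
            raise ValueError("all physical parameters must be positive")
        if self.pupil_grid % self.superpixel_size != 0:
            raise ValueError("pupil_grid must be divisible by superpixel_size")
        if not _is_power_of_two(self.field_grid):
            raise ValueError("field_grid must be a power of two")
        if self.field_grid < self.pupil_grid:
            raise ValueError("field_grid must be at least pupil_grid")
        if np.sqrt(2.0) * self.nu_half >= self.medium_index / self.wavelength:
            raise ValueError("pupil corner is evanescent; reduce NA or raise "
                             "medium_index")

    # -- derived sampling ---------------------------------------------------

    @property
    def n_super(self) -> int:
        """Superpixels per side."""
        return self.pupil_grid // self.superpixel_size

    @property
    def superpixel_grid(self) -> tuple[int, int]:
        return (self.n_super, self.n_super)

    @property
    def nu_half(self) -> float:
        """Half-extent of the pupil square in spatial frequency (1/µm)."""
        return self.numerical_aperture / (np.sqrt(2.0) * self.wavelength)

    @property
    def dnu(self) -> float:
        return 2.0 * self.nu_half / self.pupil_grid

    @property
    def focal_pixel_pitch(self) -> float:
        """Focal-plane sample pitch in µm (derived; see module docstring)."""
        return 1.0 / (self.field_grid * self.dnu)

    @property
    def fov(self) -> float:
        """Unaliased focal-plane extent in µm."""
        return 1.0 / self.dnu

    def nu_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Centered spatial-frequency axes of the full field grid (1/µm)."""
        n = self.field_grid
        ax = (np.arange(n) - n // 2) * self.dnu
        return ax, ax

    @property
    def pupil_slice(self) -> slice:
        """Slice embedding the pupil square centrally in the field grid."""
        start = (self.field_grid - self.pupil_grid) // 2
        return slice(start, start + self.pupil_grid)

    # -- presets ------------------------------------------------------------

    @classmethod
    def desk(cls, n_super: int = 32, superpixel_size: int = 4,
             field_grid: int = 256, **kw) -> "OpticalConfig":
        """Small configuration for fast experimentation and the test suite."""
        return cls(pupil_grid=n_super * superpixel_size,
                   superpixel_size=superpixel_size,
                   field_grid=field_grid, **kw)

    @classmethod
    def benchmark(cls) -> "OpticalConfig":
        """Full paper-scale geometry (100x100 superpixels of 8x8 mirrors)."""
        return cls()
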