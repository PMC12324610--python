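"""Fluorescent phantoms for the virtual microscope.

A phantom is a non-negative 3-D fluorophore-concentration map (arbitrary
units) on a regular lateral grid with explicit slice z-positions.  The
built-in kinds emulate the samples used to characterise scattering
correction: sub-micron fluorescent beads (single or fields) and micron-scale
filaments standing in for axons and capillaries.  "Diameter" throughout means
the FWHM of the Gaussian profile used to rasterise the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["Phantom", "make_phantom", "point_phantom"]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # = 2.3548.. sigma -> FWHM


@dataclass(frozen=True)
class Phantom:
    """3-D concentration map.

    ``values`` has shape (nz, ny, nx); ``xy_pitch`` is the lateral voxel
    pitch in µm; ``z_positions`` gives each slice's axial position in µm
    relative to the nominal focal plane (positive toward the objective);
    ``origin`` offsets the lateral grid center in µm.
    """

    values: np.ndarray
    xy_pitch: float
    z_positions: np.ndarray
    kind: str = "manual"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("phantom values must be 3-D (nz, ny, nx)")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("concentration must be finite and non-negative")
        z = np.atleast_1d(np.asarray(self.z_positions, dtype=float))
        if z.shape[0] != v.shape[0]:
            raise ValueError("one z position per slice required")
        if self.xy_pitch <= 0:
            raise ValueError("voxel pitch must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "z_positions", z)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def xy_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) axes of the lateral grid in µm."""
        nz, ny, nx = self.values.shape
        y0, x0 = self.origin[1], self.origin[0]
        ys = (np.arange(ny) - (ny - 1) / 2.0) * self.xy_pitch + y0
        xs = (np.arange(nx) - (nx - 1) / 2.0) * self.xy_pitch + x0
        return ys, xs


def point_phantom(position=(0.0, 0.0, 0.0), amplitude: float = 1.0,
                  xy_pitch: float = 0.1) -> Phantom:
    """Single-voxel emitter at ``position = (x, y, z)`` µm."""
    x, y, z = position
    return Phantom(np.full((1, 1, 1), float(amplitude)), xy_pitch,
                   np.array([z]), kind="bead", origin=(x, y))


def _bead_values(shape, pitches, center, sigma, amplitude):
    nz, ny, nx = shape
    dz, dy, dx = pitches
    cz, cy, cx = center
    zz = (np.arange(nz) - (nz - 1) / 2.0) * dz - cz
    yy = (np.arange(ny) - (ny - 1) / 2.0) * dy - cy
    xx = (np.arange(nx) - (nx - 1) / 2.0) * dx - cx
    r2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
          + xx[None, None, :] ** 2)
    return amplitude * np.exp(-r2 / (2.0 * sigma ** 2))


def make_phantom(kind: str, params: dict | None = None, seed: int = 0) -> Phantom:
    """Deterministic phantom generator.

    Kinds
    -----
    bead : single Gaussian blob.  params: diameter (FWHM µm, default 0.71),
        amplitude, xy_pitch, z_pitch, n_sigma (grid half-extent in sigmas),
        position (x, y, z).
    bead_field : ``n`` beads at uniform random positions in a box.
        params: n, box (x, y, z half-extents µm), diameter, xy_pitch, z_pitch.
    filament : Gaussian tube of the stated diameter along a smooth random
        path (x-aligned with filtered random transverse offsets).
        params: diameter (µm, default 1.5), length, xy_pitch, z_pitch,
        wander (µm rms), amplitude.
    uniform : constant field.  params: shape, xy_pitch, z_positions, value.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "bead":
        d = float(p.get("diameter", 0.71))
        amp = float(p.get("amplitude", 1.0))
        pitch = float(p.get("xy_pitch", d / 8.0))
        zp = float(p.get("z_pitch", pitch))
        if min(d, pitch, zp) <= 0:
            raise ValueError("bead geometry must be positive")
        sigma = d / _FWHM
        ns = float(p.get("n_sigma", 4.0))
        x, y, z = p.get("position", (0.0, 0.0, 0.0))
        nxy = 2 * int(np.ceil(ns * sigma / pitch)) + 1
        nz = 2 * int(np.ceil(ns * sigma / zp)) + 1
        vals = _bead_values((nz, nxy, nxy), (zp, pitch, pitch),
                            (0.0, 0.0, 0.0), sigma, amp)
        zpos = (np.arange(nz) - (nz - 1) / 2.0) * zp + z
        return Phantom(vals, pitch, zpos, kind="bead", origin=(x, y))

    if kind == "bead_field":
        n = int(p.get("n", 5))
        bx, by, bz = p.get("box", (10.0, 10.0, 2.0))
        d = float(p.get("diameter", 0.71))
        pitch = float(p.get("xy_pitch", 0.2))
        zp = float(p.get("z_pitch", max(bz / 2.0, pitch)))
        sigma = d / _FWHM
        nxy = int(np.ceil(2 * (bx + 3 * sigma) / pitch)) | 1
        nz = max(int(np.ceil(2 * bz / zp)) | 1, 1)
        vals = np.zeros((nz, nxy, nxy))
        zpos = (np.arange(nz) - (nz - 1) / 2.0) * zp
        for _ in range(n):
            cx, cy, cz = (rng.uniform(-bx, bx), rng.uniform(-by, by),
                          rng.uniform(-bz, bz))
            vals += _bead_values((nz, nxy, nxy), (zp, pitch, pitch),
                                 (cz, cy, cx), sigma, 1.0)
        return Phantom(vals, pitch, zpos, kind="bead_field")

    if kind == "filament":
        d = float(p.get("diameter", 1.5))
        length = float(p.get("length", 20.0))
        pitch = float(p.get("xy_pitch", d / 8.0))
        zp = float(p.get("z_pitch", pitch))
        wander = float(p.get("wander", d))
        amp = float(p.get("amplitude", 1.0))
        if min(d, length, pitch, zp) <= 0:
            raise ValueError("filament geometry must be positive")
        sigma = d / _FWHM
        nx = int(np.ceil(length / pitch)) | 1
        half = 3 * sigma + 2 * wander
        nyz = 2 * int(np.ceil(half / pitch)) + 1
        nz = 2 * int(np.ceil(half / zp)) + 1
        # smooth random transverse path y(x), z(x)
        yc = gaussian_filter1d(rng.standard_normal(nx), nx / 10.0, mode="nearest")
        zc = gaussian_filter1d(rng.standard_normal(nx), nx / 10.0, mode="nearest")
        for c in (yc, zc):
            c -= c.mean()
            s = c.std()
            if s > 0:
                c *= wander / s
        yy = (np.arange(nyz) - (nyz - 1) / 2.0) * pitch
        zz = (np.arange(nz) - (nz - 1) / 2.0) * zp
        r2 = ((yy[None, :, None] - yc[None, None, :]) ** 2
              + (zz[:, None, None] - zc[None, None, :]) ** 2)
        vals = amp * np.exp(-r2 / (2.0 * sigma ** 2))
        zpos = zz
        return Phantom(vals, pitch, zpos, kind="filament")

    if kind == "uniform":
        shape = tuple(p.get("shape", (1, 32, 32)))
        pitch = float(p.get("xy_pitch", 0.44))
        zpos = np.asarray(p.get("z_positions", np.zeros(shape[0])), dtype=float)
        value = float(p.get("value", 1.0))
        return Phantom(np.full(shape, value), pitch, zpos, kind="uniform")

    raise ValueError(f"unknown phantom kind {kind!r}")
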