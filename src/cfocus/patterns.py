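"""Pupil-plane DMD masks and random sensing patterns.

The unknown of the inverse problem is a pupil-plane intensity mask resolved
at the superpixel level (default 100x100 superpixels of 8x8 mirrors).  This
module holds the mask containers, the random binary pattern generator used
for compressive acquisition, the blank / low-NA control masks, binarization
of a grayscale solution at a prescribed output-to-input power ratio, and the
equal-delivered-power normalization applied when comparing corrected and
uncorrected acquisitions.

Conventions: illumination over the DMD is uniform, so the output-to-input
power ratio of a binary mask equals its on-superpixel fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryMask",
    "GrayscaleMask",
    "PatternSet",
    "generate_random_patterns",
    "blank_mask",
    "low_na_mask",
    "binarize_mask",
    "power_ratio",
    "normalize_delivered_power",
]


@dataclass(frozen=True)
class BinaryMask:
    """Binary amplitude mask on the superpixel grid.

    ``values[i, j]`` is True where the superpixel transmits.  ``superpixel_size``
    is the mirror-block side (kept for serialization / pupil rasterisation).
    """

    values: np.ndarray
    superpixel_size: int = 8

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if v.dtype != np.bool_:
            if not np.isin(v, (0, 1)).all():
                raise ValueError("binary mask values must be 0/1")
            v = v.astype(bool)
        object.__setattr__(self, "values", v)
        if self.superpixel_size < 1:
            raise ValueError("superpixel_size must be >= 1")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def on_count(self) -> int:
        return int(self.values.sum())

    @property
    def on_fraction(self) -> float:
        return self.on_count / self.values.size


@dataclass(frozen=True)
class GrayscaleMask:
    """Real-valued mask on the superpixel grid (solver output before binarization)."""

    values: np.ndarray
    provenance: str = "manual"  # one of {"fista", "focus_init", "manual"}

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("grayscale mask values must be finite")
        object.__setattr__(self, "values", v)
        if self.provenance not in ("fista", "focus_init", "manual"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PatternSet:
    """Stack of random binary sensing patterns (the rows of the sensing matrix A)."""

    patterns: np.ndarray  # (n, S, S) boolean
    sparsity: float
    seed: int
    superpixel_size: int = 8

    def __post_init__(self):
        p = np.asarray(self.patterns)
        if p.ndim != 3 or p.dtype != np.bool_:
            raise ValueError("patterns must be a 3-D boolean stack")
        object.__setattr__(self, "patterns", p)

    def __len__(self) -> int:
        return self.patterns.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.patterns.shape[1:]

    @property
    def n_unknowns(self) -> int:
        return self.patterns.shape[1] * self.patterns.shape[2]

    def as_matrix(self, dtype=np.float32) -> np.ndarray:
        """Flattened sensing matrix A, shape (n, P), row-major superpixels."""
        return self.patterns.reshape(len(self), -1).astype(dtype)

    def subset(self, n: int) -> "PatternSet":
        """Prefix subset (first ``n`` patterns) so sweeps are nested, not resampled."""
        if not 1 <= n <= len(self):
            raise ValueError(f"subset size {n} outside 1..{len(self)}")
        return PatternSet(self.patterns[:n], self.sparsity, self.seed,
                          self.superpixel_size)

    def mask(self, i: int) -> BinaryMask:
        return BinaryMask(self.patterns[i], self.superpixel_size)


def generate_random_patterns(n: int, grid_shape: tuple[int, int] = (100, 100),
                             sparsity: float = 0.4, seed: int = 0,
                             superpixel_size: int = 8,
                             scheme: str = "uniform") -> PatternSet:
    """Draw ``n`` random binary patterns with an exact on-count per pattern.

    With the default ``scheme="uniform"`` each pattern turns on exactly
    ``round(sparsity * P)`` superpixels, positions uniform without
    replacement (fixed on-count rather than Bernoulli sampling, removing a
    nuisance variance source); such patterns are only approximately
    orthogonal in expectation.  ``scheme="hadamard"`` instead derives
    exactly orthogonal rows from a randomly permuted Hadamard matrix
    (requires ``sparsity=0.5``; on-counts are near, not exactly, P/2 when P
    is not a power of two).  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one pattern")
    if scheme == "hadamard":
        return _hadamard_patterns(n, grid_shape, sparsity, seed,
                                  superpixel_size)
    if scheme != "uniform":
        raise ValueError("scheme must be 'uniform' or 'hadamard'")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie strictly between 0 and 1 for sensing")
    rows, cols = grid_shape
    p = rows * cols
    k = int(round(sparsity * p))
    if k == 0 or k == p:
        raise ValueError("sparsity rounds to a degenerate all-off/all-on pattern")
    rng = np.random.default_rng(seed)
    stack = np.zeros((n, p), dtype=bool)
    chunk = max(1, min(n, int(2e7) // p))  # bound scratch memory
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        r = rng.random((stop - start, p))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]
        np.put_along_axis(stack[start:stop], idx, True, axis=1)
    # Pairwise-distinct check: when the pattern space C(P, k) dwarfs n^2 a
    # collision indicates a seeding bug, so fail loudly; on tiny grids
    # duplicates are statistically expected and harmless for sensing.
    from math import lgamma, log

    log_space = (lgamma(p + 1) - lgamma(k + 1) - lgamma(p - k + 1))
    if log_space > 2.0 * log(max(n, 2)) + 40.0:
        digests = {row.tobytes() for row in np.packbits(stack, axis=1)}
        if len(digests) != n:
            raise RuntimeError(
                "duplicate sensing patterns generated (seeding bug?)")
    return PatternSet(stack.reshape(n, rows, cols), sparsity, seed, superpixel_size)


def _hadamard_patterns(n, grid_shape, sparsity, seed, superpixel_size):
    from scipy.linalg import hadamard

    if sparsity != 0.5:
        raise ValueError("hadamard scheme requires sparsity=0.5")
    rows, cols = grid_shape
    p = rows * cols
    m = 1 << (p - 1).bit_length()  # next power of two >= p
    if n > m - 1:
        raise ValueError(f"at most {m - 1} orthogonal patterns exist for "
                         f"{p} superpixels")
    rng = np.random.default_rng(seed)
    h = hadamard(m)[1:, :]  # drop the all-ones row
    row_pick = rng.permutation(m - 1)[:n]
    col_pick = rng.permutation(m)[:p]
    stack = h[np.ix_(row_pick, col_pick)] > 0
    return PatternSet(stack.reshape(n, rows, cols), 0.5, seed,
                      superpixel_size)


def blank_mask(grid_shape: tuple[int, int] = (100, 100),
               superpixel_size: int = 8) -> BinaryMask:
    """All-on mask (uncorrected acquisition; output-to-input power ratio 100%)."""
    return BinaryMask(np.ones(grid_shape, dtype=bool), superpixel_size)


def low_na_mask(grid_shape: tuple[int, int], radius: int,
                superpixel_size: int = 8) -> BinaryMask:
    """Centered-disk mask emulating a reduced effective NA.

    The disk is ``{(i, j): (i - c_r)^2 + (j - c_c)^2 <= radius^2}`` with the
    center superpixel at ``(rows // 2, cols // 2)``; ``radius=0`` turns on that
    single superpixel.
    """
    rows, cols = grid_shape
    if radius < 0 or radius > min(rows, cols) // 2:
        raise ValueError("radius must lie within the grid half-width")
    ci, cj = rows // 2, cols // 2
    ii, jj = np.ogrid[:rows, :cols]
    return BinaryMask((ii - ci) ** 2 + (jj - cj) ** 2 <= radius ** 2,
                      superpixel_size)


def _topk_order(values: np.ndarray) -> np.ndarray:
    """Row-major flat indices sorted by descending value, ties by flat index."""
    flat = values.ravel()
    return np.argsort(-flat, kind="stable")


def binarize_mask(gray: GrayscaleMask, power_ratio: float,
                  superpixel_size: int = 8) -> BinaryMask:
    """Binarize a grayscale mask at a DMD output-to-input power ratio.

    Turns on exactly ``round(power_ratio * P)`` superpixels — those with the
    largest grayscale values, ties broken by value then by row-major index.
    The tie-break is deterministic, so the on-sets are nested across ratios.
    """
    if not 0.0 < power_ratio <= 1.0:
        raise ValueError("power_ratio must lie in (0, 1]")
    v = gray.values
    p = v.size
    k = int(round(power_ratio * p))
    if k == 0:
        raise ValueError("power_ratio rounds to an empty mask")
    if np.ptp(v) == 0:
        warnings.warn("grayscale mask is constant; binarization is arbitrary "
                      "up to the row-major tie-break", RuntimeWarning,
                      stacklevel=2)
    on = np.zeros(p, dtype=bool)
    on[_topk_order(v)[:k]] = True
    return BinaryMask(on.reshape(v.shape), superpixel_size)


def power_ratio(mask: BinaryMask) -> float:
    """Output-to-input power ratio under uniform illumination (= on-fraction)."""
    return mask.on_fraction


def normalize_delivered_power(mask: BinaryMask,
                              reference_power: float = 1.0) -> float:
    """Pupil-amplitude multiplier equalising delivered power with the blank mask.

    Scaling the input amplitude by ``sqrt(reference_power / power_ratio)``
    makes the power transmitted by ``mask`` equal to ``reference_power`` (the
    blank-mask delivered power, 1 by convention) — the instrument raises the
    laser power into the DMD so the power on the sample is constant with and
    without correction.
    """
    r = power_ratio(mask)
    if r == 0.0:
        raise ValueError("cannot normalize an all-off mask")
    if reference_power <= 0:
        raise ValueError("reference_power must be positive")
    return float(np.sqrt(reference_power / r))
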