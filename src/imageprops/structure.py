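"""PHOG self-similarity, mirror symmetry, and filter-response variances.

*Self-similarity* follows the PHOG (pyramid histogram of oriented gradients)
idea: the image is reduced to ~100,000 pixels, signed gradient orientations
(0-360 degrees, taken from the color channel with the largest gradient
magnitude per pixel) are binned into 16 orientation histograms for the whole
image (ground level) and for the 4/16/64 sub-rectangles of pyramid levels
1-3.  Each sub-histogram is compared with the ground histogram by histogram
intersection; self-similarity is the median over all 84 comparisons.

*Symmetry* and the *Pa/Pf variances* are computed from a fixed, deterministic
bank of 48 analytic kernels that covers luminance edges/texture (12
orientations x odd/even phase) and color opponency (12 oriented odd kernels
on each of the R-G and B-Y planes).  Responses are rectified and max-pooled
into an S x S grid.  Left-right symmetry compares the grid with its
column-reversed, filter-mirrored copy (1 = perfect mirror symmetry);
up-down symmetry uses row reversal.  Pa is the variance across filters of
the cell-averaged normalized responses (low Pa = many filters respond =
"richness"); Pf is the mean across filters of the variance of normalized
responses across cells (response variability over image sections).

The analytic bank stands in for first-layer features of a pretrained
convolutional network: it removes a model-weights dependency while keeping
the color/edge/texture coverage such features provide, at the cost of
absolute Pa/Pf scales being implementation-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from skimage.filters import gabor_kernel

from ._filters import bank_convolve
from .io import RasterImage, resize_to_area, to_gray

__all__ = [
    "HogPyramid",
    "FilterResponseGrid",
    "SymmetryScores",
    "CnnVariances",
    "hog_pyramid",
    "self_similarity",
    "filter_response_grid",
    "symmetry_scores",
    "cnn_variances",
]

PHOG_BINS = 16
PHOG_TARGET_PIXELS = 100_000
PHOG_LEVELS = (1, 2, 3)


# ---------------------------------------------------------------------------
# PHOG self-similarity


@dataclass(frozen=True)
class HogPyramid:
    """Ground-level and level 1-3 orientation histograms (16 bins, 0-360 deg).

    ``levels`` maps level L to an array of shape (2^L, 2^L, 16); rows of the
    array that had no gradient energy are flagged in ``empty`` and excluded
    from self-similarity.
    """

    ground: np.ndarray
    levels: dict[int, np.ndarray]
    empty: dict[int, np.ndarray]


def _signed_gradient(px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and signed orientation (0-360 deg).

    The gradient is taken per color channel; each pixel keeps the channel
    with the maximal magnitude (standard PHOG practice for color images).
    """
    gy, gx = np.gradient(px, axis=(0, 1))
    mag = np.hypot(gx, gy)
    best = mag.argmax(axis=2)
    take = lambda a: np.take_along_axis(a, best[..., None], axis=2)[..., 0]
    m = take(mag)
    ori = np.mod(np.degrees(np.arctan2(take(gy), take(gx))), 360.0)
    return m, ori


def _hist16(mag: np.ndarray, ori: np.ndarray) -> tuple[np.ndarray, bool]:
    total = mag.sum()
    if total <= 0:
        return np.zeros(PHOG_BINS), True
    h, _ = np.histogram(ori, bins=PHOG_BINS, range=(0.0, 360.0), weights=mag)
    return h / total, False


def hog_pyramid(img: RasterImage, target_pixels: int = PHOG_TARGET_PIXELS) -> HogPyramid:
    """Normalized 16-bin orientation histograms for the PHOG pyramid."""
    small = resize_to_area(img, target_pixels)
    mag, ori = _signed_gradient(small.pixels)
    ground, ground_empty = _hist16(mag, ori)
    if ground_empty:
        raise ValueError(f"featureless image {img.id!r}: zero gradient energy")
    h, w = mag.shape
    levels: dict[int, np.ndarray] = {}
    empty: dict[int, np.ndarray] = {}
    for lvl in PHOG_LEVELS:
        k = 2**lvl
        ys = np.linspace(0, h, k + 1).astype(int)
        xs = np.linspace(0, w, k + 1).astype(int)
        hists = np.zeros((k, k, PHOG_BINS))
        emp = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                block = slice(ys[i], ys[i + 1]), slice(xs[j], xs[j + 1])
                hists[i, j], emp[i, j] = _hist16(mag[block], ori[block])
        levels[lvl] = hists
        empty[lvl] = emp
    return HogPyramid(ground, levels, empty)


def self_similarity(pyramid: HogPyramid, aggregate: str = "median") -> float:
    """Median (or mean) histogram intersection of sub-histograms with ground."""
    sims = []
    for lvl, hists in pyramid.levels.items():
        emp = pyramid.empty[lvl]
        for i in range(hists.shape[0]):
            for j in range(hists.shape[1]):
                if not emp[i, j]:
                    sims.append(np.minimum(hists[i, j], pyramid.ground).sum())
    if not sims:
        raise ValueError("no non-empty sub-histograms")
    if aggregate == "median":
        return float(np.median(sims))
    if aggregate == "mean":
        return float(np.mean(sims))
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------------------
# Filter-response grid: symmetry and Pa/Pf variances

GRID_ORIENTATIONS = 12
GRID_WAVELENGTH = 8.0
GRID_SIZE = 8


@lru_cache(maxsize=4)
def _grid_kernels(n_orient: int, wavelength: float) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """(odd kernels, even kernels) at ``n_orient`` angles over 180 degrees."""
    odd, even = [], []
    for k in range(n_orient):
        theta = np.deg2rad(k * 180.0 / n_orient)
        g = gabor_kernel(frequency=1.0 / wavelength, theta=theta, bandwidth=1.0)
        odd.append(np.imag(g))
        even.append(np.real(g) - np.real(g).mean())  # DC-free
    return odd, even


def _mirror_partner(n_orient: int) -> np.ndarray:
    """Filter-index permutation under left-right or up-down mirroring.

    theta -> 180 - theta (lr) and theta -> -theta (ud) both map orientation
    index k to (n - k) mod n for angles at k * 180/n.
    """
    k = np.arange(n_orient)
    return (n_orient - k) % n_orient


@dataclass(frozen=True)
class FilterResponseGrid:
    """Rectified, max-pooled responses: shape (F, S, S), F = 48 by default.

    ``mirror_map`` gives, for each filter index, the index of its
    orientation-mirrored partner (identical for lr and ud mirroring with
    this bank).
    """

    responses: np.ndarray
    mirror_map: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.responses < 0):
            raise ValueError("pooled responses must be non-negative")

    @property
    def n_filters(self) -> int:
        return self.responses.shape[0]


def _pool_max(resp: np.ndarray, s: int) -> np.ndarray:
    """Max-pool (F, H, W) -> (F, s, s) with mirror-symmetric cell boundaries."""
    f, h, w = resp.shape

    def bounds(n: int) -> np.ndarray:
        b = np.zeros(s + 1, dtype=int)
        for i in range(s // 2 + 1):
            b[i] = int(round(i * n / s))
            b[s - i] = n - b[i]
        return b

    ys, xs = bounds(h), bounds(w)
    out = np.zeros((f, s, s))
    for i in range(s):
        for j in range(s):
            out[:, i, j] = resp[:, ys[i] : ys[i + 1], xs[j] : xs[j + 1]].max(axis=(1, 2))
    return out


def filter_response_grid(img: RasterImage, grid_size: int = GRID_SIZE) -> FilterResponseGrid:
    """48-kernel rectified responses max-pooled into a grid_size^2 layout.

    Kernel order: 12 odd luminance, 12 even luminance, 12 odd on R-G,
    12 odd on B-Y.  The mirror partner of each kernel lies within its own
    block of 12 (orientation map k -> (12-k) mod 12).
    """
    px = img.pixels
    lum = to_gray(img)
    rg = px[..., 0] - px[..., 1]
    by = px[..., 2] - 0.5 * (px[..., 0] + px[..., 1])
    odd, even = _grid_kernels(GRID_ORIENTATIONS, GRID_WAVELENGTH)
    blocks = [
        bank_convolve(lum, odd, ("grid_odd", GRID_ORIENTATIONS, GRID_WAVELENGTH)),
        bank_convolve(lum, even, ("grid_even", GRID_ORIENTATIONS, GRID_WAVELENGTH)),
        bank_convolve(rg, odd, ("grid_odd", GRID_ORIENTATIONS, GRID_WAVELENGTH)),
        bank_convolve(by, odd, ("grid_odd", GRID_ORIENTATIONS, GRID_WAVELENGTH)),
    ]
    resp = np.abs(np.concatenate(blocks, axis=0))
    pooled = _pool_max(resp, grid_size)
    partner = _mirror_partner(GRID_ORIENTATIONS)
    mirror_map = np.concatenate(
        [partner + 12 * b for b in range(4)]
    )
    return FilterResponseGrid(pooled, mirror_map)


@dataclass(frozen=True)
class SymmetryScores:
    sym_lr: float
    sym_ud: float


def _mirror_grid(grid: FilterResponseGrid, axis: str) -> np.ndarray:
    g = grid.responses[grid.mirror_map]
    return g[:, :, ::-1] if axis == "lr" else g[:, ::-1, :]


def _sym_score(g: np.ndarray, m: np.ndarray) -> float:
    denom = g.sum() + m.sum()
    if denom <= 0:
        return 1.0
    return float(1.0 - np.abs(g - m).sum() / denom)


def symmetry_scores(img: RasterImage, grid: FilterResponseGrid | None = None) -> SymmetryScores:
    """Left-right and up-down mirror symmetry in [0, 1] (1 = perfect)."""
    import warnings

    if grid is None:
        grid = filter_response_grid(img)
    if grid.responses.sum() <= 0:
        warnings.warn(f"featureless image {img.id!r}: symmetry defined as 1.0", stacklevel=2)
        return SymmetryScores(1.0, 1.0)
    g = grid.responses
    return SymmetryScores(
        _sym_score(g, _mirror_grid(grid, "lr")),
        _sym_score(g, _mirror_grid(grid, "ud")),
    )


@dataclass(frozen=True)
class CnnVariances:
    var_pa: float
    var_pf: float


def cnn_variances(grid: FilterResponseGrid) -> CnnVariances:
    """Pa and Pf variances of the per-cell normalized response grid.

    Responses are normalized per cell to sum 1 over filters (cells with zero
    energy are dropped); ``a[f]`` is the cell-average per filter.  Pa is the
    population variance of ``a`` over filters; Pf is the mean over filters of
    the variance over cells.
    """
    f = grid.n_filters
    flat = grid.responses.reshape(f, -1)
    energy = flat.sum(axis=0)
    if energy.sum() <= 0:
        raise ValueError("zero total filter response")
    cells = flat[:, energy > 0] / energy[energy > 0]
    a = cells.mean(axis=1)
    var_pa = float(np.var(a))
    var_pf = float(np.var(cells, axis=1).mean())
    return CnnVariances(var_pa, var_pf)
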