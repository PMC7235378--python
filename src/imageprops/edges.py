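"""Gabor edge maps, edge density, and edge-orientation entropies.

A bank of odd-symmetric (edge-sensitive) Gabor kernels at ``n_orientations``
angles over 0-180 degrees and several spatial wavelengths is convolved with
the luminance image.  Each pixel is assigned the maximal absolute response
over the bank (its edge *magnitude*) and a signed edge orientation in
[0, 360): the tangent direction of the winning filter, plus 180 degrees when
the signed response is negative, so that edge polarity is preserved.

From the edge map follow three global properties:

* **edge density** -- the summed edge magnitude per pixel (x1000), a measure
  of image complexity;
* **first-order entropy** -- the Shannon entropy (bits) of the
  magnitude-weighted orientation histogram: maximal (log2 B) when all
  orientations are equally represented, small when a few dominate;
* **second-order entropy** -- the mean, over distance annuli, of the entropy
  of pairwise orientation *differences* between the strongest edge elements:
  maximal when orientations at different positions are mutually
  unpredictable, near zero when the whole image is coherently oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import entropy as _shannon
from skimage.filters import gabor_kernel

from ._filters import bank_convolve
from .io import GrayImage

__all__ = [
    "GaborBank",
    "EdgeMap",
    "OrientationHistogram",
    "gabor_edge_map",
    "edge_density",
    "orientation_histogram",
    "first_order_entropy",
    "second_order_entropy",
]

DEFAULT_ANNULI: tuple[tuple[float, float], ...] = ((0, 20), (20, 40), (40, 80), (80, 160))


@dataclass(frozen=True)
class GaborBank:
    """Odd-symmetric Gabor bank: ``n_orientations`` angles over 0-180 degrees.

    The signed response doubles the orientation range to 0-360 degrees.
    ``bandwidth`` is the spatial-frequency bandwidth in octaves.
    """

    n_orientations: int = 24
    wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0)
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.n_orientations < 8:
            raise ValueError("n_orientations must be >= 8")
        if list(self.wavelengths) != sorted(self.wavelengths) or min(self.wavelengths) <= 0:
            raise ValueError("wavelengths must be positive and ascending")

    @property
    def thetas_deg(self) -> np.ndarray:
        return np.arange(self.n_orientations) * (180.0 / self.n_orientations)

    def kernels(self) -> list[np.ndarray]:
        return _bank_kernels(self.n_orientations, self.wavelengths, self.bandwidth)

    def key(self) -> tuple:
        return ("edge_bank", self.n_orientations, self.wavelengths, self.bandwidth)


@lru_cache(maxsize=8)
def _bank_kernels(
    n_orientations: int, wavelengths: tuple[float, ...], bandwidth: float
) -> list[np.ndarray]:
    kernels = []
    for lam in wavelengths:
        for k in range(n_orientations):
            theta = np.deg2rad(k * 180.0 / n_orientations)
            kernels.append(
                np.imag(gabor_kernel(frequency=1.0 / lam, theta=theta, bandwidth=bandwidth))
            )
    return kernels


@dataclass(frozen=True)
class EdgeMap:
    """Per-pixel edge magnitude (max over the bank) and signed orientation.

    ``orientation`` is in degrees in [0, 360); it is only meaningful where
    ``magnitude`` > 0.
    """

    magnitude: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.orientation.shape:
            raise ValueError("magnitude and orientation must have the same shape")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


def gabor_edge_map(gray: GrayImage, bank: GaborBank | None = None) -> EdgeMap:
    """Maximal odd-Gabor response and its signed orientation per pixel.

    The edge orientation is the *tangent* of the luminance edge: a vertical
    step edge yields orientations in the 90-degree (or 270-degree) band.

    A border margin of min(largest kernel radius, min(H, W)//8) pixels is
    excluded from the returned map: responses there depend on the boundary
    extrapolation rather than on image content, which distorts both the
    orientation histogram and the pairwise statistics.
    """
    if bank is None:
        bank = GaborBank()
    g = np.asarray(gray, dtype=float)
    responses = bank_convolve(g, bank.kernels(), bank.key())
    radius = max(max(k.shape) for k in bank.kernels()) // 2
    margin = min(radius, min(g.shape) // 8)
    if margin > 0:
        responses = responses[:, margin:-margin, margin:-margin]
        g = g[margin:-margin, margin:-margin]
    absresp = np.abs(responses)
    flat = absresp.reshape(len(responses), -1)
    winner = flat.argmax(axis=0)
    magnitude = np.take_along_axis(flat, winner[None, :], axis=0)[0].reshape(g.shape)
    signed = np.take_along_axis(
        responses.reshape(len(responses), -1), winner[None, :], axis=0
    )[0].reshape(g.shape)
    # winner index -> filter angle; +90 converts propagation axis to edge tangent
    theta = bank.thetas_deg[winner % bank.n_orientations].reshape(g.shape)
    orientation = np.mod(theta + 90.0 + np.where(signed < 0, 180.0, 0.0), 360.0)
    orientation = np.where(magnitude > 0, orientation, 0.0)
    return EdgeMap(magnitude, orientation)


def edge_density(edges: EdgeMap) -> float:
    """Summed edge magnitude per pixel, scaled x1000 (per-mille units)."""
    return float(edges.magnitude.sum() / edges.magnitude.size * 1000.0)


@dataclass(frozen=True)
class OrientationHistogram:
    """Magnitude-weighted orientation distribution over B equal bins of 360 deg."""

    mass: np.ndarray
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_edges is None:
            object.__setattr__(
                self, "bin_edges", np.linspace(0.0, 360.0, len(self.mass) + 1)
            )
        if np.any(self.mass < -1e-12):
            raise ValueError("histogram mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.mass)


def orientation_histogram(edges: EdgeMap, n_bins: int = 24) -> OrientationHistogram:
    """Magnitude-weighted histogram of edge orientations, normalized to sum 1."""
    total = edges.magnitude.sum()
    if total <= 0:
        raise ValueError("no edges: total edge magnitude is zero")
    counts, _ = np.histogram(
        edges.orientation, bins=n_bins, range=(0.0, 360.0), weights=edges.magnitude
    )
    return OrientationHistogram(counts / total)


def first_order_entropy(hist: OrientationHistogram) -> float:
    """Shannon entropy (bits) of the orientation distribution."""
    return float(_shannon(hist.mass, base=2))


def second_order_entropy(
    edges: EdgeMap,
    n_bins: int = 24,
    n_top: int = 10_000,
    annuli: tuple[tuple[float, float], ...] = DEFAULT_ANNULI,
) -> float:
    """Mean entropy (bits) of pairwise orientation differences by distance.

    The ``n_top`` strongest edge elements are selected (ties broken by
    row-major pixel order).  For each distance annulus ``(d_lo, d_hi]`` a
    histogram of the orientation differences ``o_j - o_i (mod 360)`` over all
    ordered pairs with separation in the annulus is accumulated; the result
    is the mean Shannon entropy over non-empty annuli.  Raises if every
    annulus contains fewer than 100 ordered pairs.
    """
    mag = edges.magnitude.ravel()
    nz = np.flatnonzero(mag > 0)
    if len(nz) < 2:
        raise ValueError("image too sparse: fewer than 2 nonzero edge elements")
    order = nz[np.argsort(-mag[nz], kind="stable")][:n_top]
    h, w = edges.magnitude.shape
    ys = (order // w).astype(np.float64)
    xs = (order % w).astype(np.float64)
    obin = np.floor(edges.orientation.ravel()[order] / (360.0 / n_bins)).astype(np.int64)
    obin = np.clip(obin, 0, n_bins - 1)
    n = len(order)
    counts = np.zeros((len(annuli), n_bins), dtype=np.int64)
    chunk = max(1, int(4e6) // n)
    lo = np.array([a[0] for a in annuli])
    hi = np.array([a[1] for a in annuli])
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = np.hypot(ys[sl, None] - ys[None, :], xs[sl, None] - xs[None, :])
        # ordered pairs i != j; self-pairs have d == 0 and are excluded by d > lo >= 0
        diff = np.mod(obin[None, :] - obin[sl, None], n_bins)
        for a in range(len(annuli)):
            m = (d > lo[a]) & (d <= hi[a])
            if m.any():
                counts[a] += np.bincount(diff[m], minlength=n_bins)
    totals = counts.sum(axis=1)
    if np.all(totals < 100):
        raise ValueError("image too sparse: fewer than 100 pairs in every annulus")
    ents = [
        _shannon(counts[a] / totals[a], base=2) for a in range(len(annuli)) if totals[a] > 0
    ]
    return float(np.mean(ents))
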