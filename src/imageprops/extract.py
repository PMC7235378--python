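"""Per-image computation of the 13 global image properties.

The 13 properties are the mean HSV channel values (h_mean, s_mean, v_mean),
left-right and up-down mirror symmetry (sym_lr, sym_ud), edge density,
PHOG self-similarity, the slope and sigma of the radially averaged log-log
Fourier power spectrum, the first- and second-order edge-orientation
entropies, and the Pa/Pf filter-response variances.

:func:`extract_features` computes them for one image;
:class:`GlobalImagePropertyExtractor` is a scikit-learn transformer that maps
a sequence of images to an (n, 13) feature table and composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import color, edges, spectral, structure
from .io import FEATURE_NAMES, RasterImage, load_image, to_gray

__all__ = [
    "FeatureConfig",
    "extract_features",
    "extract_table",
    "GlobalImagePropertyExtractor",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the 13 extractors (defaults as documented)."""

    n_orientations: int = 24
    wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0)
    orientation_bins: int = 24
    n_top: int = 10_000
    annuli: tuple[tuple[float, float], ...] = edges.DEFAULT_ANNULI
    spectral_bins: int = 20
    fit_range: tuple[float, float] | None = None
    window: str | None = None
    phog_target_pixels: int = 100_000
    self_similarity_aggregate: str = "median"
    grid_size: int = 8
    circular_hue: bool = False

    def bank(self) -> edges.GaborBank:
        return edges.GaborBank(self.n_orientations, tuple(self.wavelengths))


def extract_features(
    img: RasterImage, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All 13 global properties of one image, keyed by canonical name."""
    cfg = config or FeatureConfig()
    out: dict[str, float] = {}

    cm = color.hsv_means(img, circular_hue=cfg.circular_hue)
    out["h_mean"], out["s_mean"], out["v_mean"] = cm.h_mean, cm.s_mean, cm.v_mean

    grid = structure.filter_response_grid(img, grid_size=cfg.grid_size)
    sym = structure.symmetry_scores(img, grid=grid)
    out["sym_lr"], out["sym_ud"] = sym.sym_lr, sym.sym_ud
    var = structure.cnn_variances(grid)
    out["var_pa"], out["var_pf"] = var.var_pa, var.var_pf

    pyramid = structure.hog_pyramid(img, target_pixels=cfg.phog_target_pixels)
    out["self_similarity"] = structure.self_similarity(
        pyramid, aggregate=cfg.self_similarity_aggregate
    )

    gray = to_gray(img)
    fit = spectral.spectral_fit(
        gray, n_bins=cfg.spectral_bins, fit_range=cfg.fit_range, window=cfg.window
    )
    out["fourier_slope"], out["fourier_sigma"] = fit.slope, fit.sigma

    em = edges.gabor_edge_map(gray, cfg.bank())
    out["edge_density"] = edges.edge_density(em)
    hist = edges.orientation_histogram(em, n_bins=cfg.orientation_bins)
    out["entropy1"] = edges.first_order_entropy(hist)
    out["entropy2"] = edges.second_order_entropy(
        em, n_bins=cfg.orientation_bins, n_top=cfg.n_top, annuli=cfg.annuli
    )
    return {k: out[k] for k in FEATURE_NAMES}


def extract_table(
    images: Iterable[RasterImage], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table (id index, 13 columns) for a sequence of images."""
    rows, ids = [], []
    for img in images:
        rows.append(extract_features(img, config))
        ids.append(img.id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=list(FEATURE_NAMES))


class GlobalImagePropertyExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: images -> 13 global image properties.

    ``X`` may be a sequence of :class:`RasterImage`, (H, W, 3) arrays in
    [0, 1], or file paths.  ``transform`` returns an (n, 13) float array in
    the canonical feature order (see ``get_feature_names_out``).  The
    transformer is stateless; ``fit`` only validates parameters.

    Examples
    --------
    >>> from imageprops.synthetic import gen_powerlaw_image
    >>> ext = GlobalImagePropertyExtractor()
    >>> X = ext.fit_transform([gen_powerlaw_image(64, -2.0, seed=0)])
    >>> X.shape
    (1, 13)
    """

    def __init__(
        self,
        n_orientations: int = 24,
        wavelengths: tuple[float, ...] = (4.0, 8.0, 16.0),
        orientation_bins: int = 24,
        n_top: int = 10_000,
        spectral_bins: int = 20,
        fit_range: tuple[float, float] | None = None,
        phog_target_pixels: int = 100_000,
        self_similarity_aggregate: str = "median",
        grid_size: int = 8,
        circular_hue: bool = False,
    ) -> None:
        self.n_orientations = n_orientations
        self.wavelengths = wavelengths
        self.orientation_bins = orientation_bins
        self.n_top = n_top
        self.spectral_bins = spectral_bins
        self.fit_range = fit_range
        self.phog_target_pixels = phog_target_pixels
        self.self_similarity_aggregate = self_similarity_aggregate
        self.grid_size = grid_size
        self.circular_hue = circular_hue

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            n_orientations=self.n_orientations,
            wavelengths=tuple(self.wavelengths),
            orientation_bins=self.orientation_bins,
            n_top=self.n_top,
            spectral_bins=self.spectral_bins,
            fit_range=self.fit_range,
            phog_target_pixels=self.phog_target_pixels,
            self_similarity_aggregate=self.self_similarity_aggregate,
            grid_size=self.grid_size,
            circular_hue=self.circular_hue,
        )

    @staticmethod
    def _as_image(item, i: int) -> RasterImage:
        if isinstance(item, RasterImage):
            return item
        if isinstance(item, (str, Path)):
            return load_image(item)
        return RasterImage(np.asarray(item, dtype=float), id=str(i))

    def fit(self, X: Sequence | None = None, y=None) -> "GlobalImagePropertyExtractor":
        self._config()  # parameter validation
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        cfg = self._config()
        images = [self._as_image(item, i) for i, item in enumerate(X)]
        table = extract_table(images, cfg)
        return table.to_numpy()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
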