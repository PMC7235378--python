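"""Image and table input/output shared by every feature extractor.

Images are carried as :class:`RasterImage`, an RGB pixel array with values in
[0, 1].  Grayscale images are plain 2-D float arrays in [0, 1] (``GrayImage``
is a type alias).  Ratings live in :class:`RatingTable`, a thin wrapper around
a pandas DataFrame that also records the rating scale of each term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

__all__ = [
    "RasterImage",
    "GrayImage",
    "RatingTable",
    "FEATURE_NAMES",
    "load_image",
    "to_gray",
    "resize_to_area",
    "read_ratings",
    "write_features",
    "read_features",
]

#: The 13 global image properties, in canonical column order.
FEATURE_NAMES = (
    "h_mean",
    "s_mean",
    "v_mean",
    "sym_lr",
    "sym_ud",
    "edge_density",
    "self_similarity",
    "fourier_slope",
    "fourier_sigma",
    "entropy1",
    "entropy2",
    "var_pa",
    "var_pf",
)

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

MIN_IMAGE_SIDE = 8

GrayImage = np.ndarray  # H x W floats in [0, 1]


@dataclass(frozen=True)
class RasterImage:
    """An RGB image with pixel values in [0, 1].

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Channel values in [0, 1].
    id : str
        Label used to key feature and rating tables.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RasterImage expects an H x W x 3 array, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image {self.id!r} is degenerate: {px.shape[0]}x{px.shape[1]} "
                f"(both sides must be >= {MIN_IMAGE_SIDE})"
            )
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError(f"image {self.id!r} has channel values outside [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


def load_image(path: str | Path, id: str | None = None) -> RasterImage:
    """Load a raster image (PNG/JPEG/BMP/TIFF) and rescale it to [0, 1].

    Grayscale sources are replicated to three identical channels; an alpha
    channel, if present, is discarded.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, UnidentifiedImageError, SyntaxError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return RasterImage(arr, id=id if id is not None else path.stem)


def to_gray(img: RasterImage | np.ndarray) -> GrayImage:
    """Convert to luminance using BT.601 weights (0.299, 0.587, 0.114)."""
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    w = np.asarray(BT601_WEIGHTS)
    return px @ w


def resize_to_area(img: RasterImage, target_pixels: int = 100_000) -> RasterImage:
    """Downscale so that width*height is close to ``target_pixels``.

    Aspect ratio is preserved and bilinear interpolation (with anti-aliasing)
    is used.  Images that are already at or below the target are returned
    unchanged: there is no upsampling.
    """
    if target_pixels < 64:
        raise ValueError("target_pixels must be >= 64")
    if img.n_pixels <= target_pixels:
        return img
    scale = np.sqrt(target_pixels / img.n_pixels)
    new_h = max(MIN_IMAGE_SIDE, int(round(img.height * scale)))
    new_w = max(MIN_IMAGE_SIDE, int(round(img.width * scale)))
    out = _sk_resize(
        img.pixels, (new_h, new_w), order=1, anti_aliasing=True, preserve_range=True
    )
    return RasterImage(np.clip(out, 0.0, 1.0), id=img.id)


@dataclass
class RatingTable:
    """Per-image affective ratings with their scale ranges.

    ``data`` is indexed by image id and has one column per rating term
    (e.g. valence, arousal).  ``scales`` maps each term to its
    (scale_min, scale_max) range; every finite rating must lie inside it.
    """

    data: pd.DataFrame
    scales: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate image ids in ratings table: {dupes}")
        if not self.scales:
            self.scales = {
                t: (float(self.data[t].min()), float(self.data[t].max()))
                for t in self.data.columns
            }
        for term in self.data.columns:
            lo, hi = self.scales.get(term, (-np.inf, np.inf))
            col = self.data[term]
            bad = col[(col.notna()) & ((col < lo) | (col > hi))]
            if len(bad):
                raise ValueError(
                    f"rating {term!r} outside declared scale [{lo}, {hi}] "
                    f"for ids {bad.index.tolist()[:5]}"
                )
        n_missing = int(self.data.isna().sum().sum())
        if n_missing:
            warnings.warn(
                f"ratings table has {n_missing} missing cells", stacklevel=2
            )

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def read_ratings(
    path: str | Path,
    scales: Mapping[str, tuple[float, float]] | tuple[float, float] | None = None,
    id_column: str = "id",
    sep: str | None = None,
) -> RatingTable:
    """Read a delimited ratings table (comma default, tab accepted).

    Parameters
    ----------
    scales
        Either a mapping ``term -> (lo, hi)``, a single ``(lo, hi)`` applied
        to every term, or None to take the observed range per term.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"ratings file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"ratings table {path} lacks an {id_column!r} column")
    df[id_column] = df[id_column].astype(str)
    df = df.set_index(id_column)
    df = df.apply(pd.to_numeric)
    if scales is None:
        scale_map: dict[str, tuple[float, float]] = {}
    elif isinstance(scales, tuple):
        scale_map = {t: (float(scales[0]), float(scales[1])) for t in df.columns}
    else:
        scale_map = {t: (float(lo), float(hi)) for t, (lo, hi) in scales.items()}
    return RatingTable(df, scale_map)


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (id index, 13 feature columns) as CSV.

    Floats are written with shortest round-trip repr, so a read-back
    reproduces every value exactly.
    """
    df = table.copy()
    df.index.name = "id"
    df.to_csv(path)


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_features`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"feature file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError(f"feature table {path} lacks an 'id' column")
    df["id"] = df["id"].astype(str)
    return df.set_index("id")
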