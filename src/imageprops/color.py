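"""Mean HSV channel values.

Color is summarized in the hue-saturation-value space (standard hexcone
model, all three channels scaled to [0, 1]).  The per-image statistic is the
arithmetic mean of each channel over all pixels.  Hue is averaged
arithmetically on [0, 1] by default -- i.e. with a discontinuity at red --
mirroring the plain channel-mean computed by common toolbox rgb2hsv
pipelines; a circular mean is available as an option.  Achromatic pixels
(S = 0) carry H = 0 and are not excluded from the hue mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .io import RasterImage

__all__ = ["ColorMeans", "hsv_means"]


@dataclass(frozen=True)
class ColorMeans:
    h_mean: float
    s_mean: float
    v_mean: float


def hsv_means(img: RasterImage, circular_hue: bool = False) -> ColorMeans:
    """Mean H, S and V channel values of an RGB image.

    Parameters
    ----------
    circular_hue
        If True, the hue mean is the circular mean of 2*pi*H mapped back to
        [0, 1); the default is the arithmetic mean.
    """
    hsv = rgb2hsv(img.pixels)
    h = hsv[..., 0]
    if circular_hue:
        ang = 2 * np.pi * h
        h_mean = float(np.mod(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()), 2 * np.pi) / (2 * np.pi))
    else:
        h_mean = float(h.mean())
    return ColorMeans(h_mean, float(hsv[..., 1].mean()), float(hsv[..., 2].mean()))
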