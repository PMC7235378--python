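"""Shared FFT-based filter-bank convolution.

All filter-bank operations (edge maps, pooled response grids) convolve one
image with dozens of Gabor kernels.  Doing this kernel-by-kernel with spatial
convolution is prohibitively slow for corpus-scale runs, so the image is
edge-replicated (to avoid the spurious border gradients that zero or mirror
padding would create), transformed once with a real FFT, multiplied with
cached kernel spectra, and transformed back per kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

# cache: (bank_key, padded_shape) -> list of kernel rffts
_KERNEL_FFT_CACHE: dict[tuple, list[np.ndarray]] = {}
_MAX_CACHE_ENTRIES = 16


def bank_convolve(
    image: np.ndarray, kernels: list[np.ndarray], bank_key: tuple
) -> np.ndarray:
    """Convolve ``image`` (H, W) with every kernel; edge-replicate boundary.

    Returns an array of shape (n_kernels, H, W).  ``bank_key`` must uniquely
    identify the kernel list so spectra can be cached across images of the
    same size.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    margin = max(max(k.shape) for k in kernels) // 2
    padded = np.pad(img, margin, mode="edge")
    ph, pw = padded.shape
    fh, fw = sp_fft.next_fast_len(ph), sp_fft.next_fast_len(pw)
    key = (bank_key, fh, fw)
    spectra = _KERNEL_FFT_CACHE.get(key)
    if spectra is None:
        spectra = []
        for k in kernels:
            kh, kw = k.shape
            buf = np.zeros((fh, fw))
            buf[:kh, :kw] = k
            # center the kernel so the product is a centered convolution
            buf = np.roll(buf, (-(kh // 2), -(kw // 2)), axis=(0, 1))
            spectra.append(sp_fft.rfft2(buf))
        if len(_KERNEL_FFT_CACHE) >= _MAX_CACHE_ENTRIES:
            _KERNEL_FFT_CACHE.clear()
        _KERNEL_FFT_CACHE[key] = spectra
    buf = np.zeros((fh, fw))
    buf[:ph, :pw] = padded
    img_fft = sp_fft.rfft2(buf)
    out = np.empty((len(kernels), h, w))
    for i, kf in enumerate(spectra):
        full = sp_fft.irfft2(img_fft * kf, s=(fh, fw))
        # convolution flips the kernel; our Gabor kernels are symmetric or
        # antisymmetric, so correlation differs at most by a sign, which the
        # callers absorb (magnitudes) or account for (signed orientation).
        out[i] = full[margin : margin + h, margin : margin + w]
    return out
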