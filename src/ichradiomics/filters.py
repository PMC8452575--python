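"""Filter bank producing the 13 derived images used for feature extraction.

The derived set is the resampled original ("Intensities"), four
scale-normalised Laplacian-of-Gaussian responses, and the eight subbands of a
single-level undecimated 3-D separable wavelet transform. Names and order are
a frozen contract consumed by the feature catalogue.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .imaging import ImagingError, VolumeGrid

DEFAULT_LOG_SIGMAS_MM = (0.5, 1.5, 2.5, 3.5)
DEFAULT_WAVELET = "coif1"

#: subband letter i gives the filter (L low-pass, H high-pass) along axis i
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def log_image_name(sigma_mm: float) -> str:
    return f"LoG-{int(round(sigma_mm * 10)):02d}"


def canonical_image_names(sigmas=DEFAULT_LOG_SIGMAS_MM) -> tuple[str, ...]:
    return (
        ("Intensities",)
        + tuple(log_image_name(s) for s in sigmas)
        + tuple(f"Wavelet-{b}" for b in WAVELET_SUBBANDS)
    )


CANONICAL_IMAGE_NAMES = canonical_image_names()


def _gaussian_taps(sigma: float, truncate: float = 4.0):
    """1-D Gaussian smoothing and second-derivative kernels.

    The smoothing kernel is normalised to unit sum; the second-derivative
    kernel is corrected to exact zero sum so a constant input gives an
    exactly zero Laplacian despite kernel truncation.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    d2 = g * (x**2 - sigma**2) / sigma**4
    d2 -= d2.mean()
    return g, d2


def log_filter(vol: VolumeGrid, sigma_mm: float) -> VolumeGrid:
    """Scale-normalised Laplacian of Gaussian, reflect boundary.

    Separable implementation: for each axis, the second derivative of the
    Gaussian along that axis times plain Gaussian smoothing along the other
    two, summed over axes, then multiplied by sigma^2 so blob responses are
    comparable across scales.
    """
    if sigma_mm <= 0:
        raise ValueError(f"sigma_mm must be positive, got {sigma_mm}")
    sigma_vox = [sigma_mm / s for s in vol.spacing]
    taps = [_gaussian_taps(s) for s in sigma_vox]
    out = np.zeros_like(vol.data)
    for deriv_axis in range(3):
        part = vol.data
        for axis in range(3):
            g, d2 = taps[axis]
            k = d2 if axis == deriv_axis else g
            part = ndimage.correlate1d(part, k, axis=axis, mode="reflect")
        out += part
    out *= sigma_mm**2
    return VolumeGrid(out, vol.spacing, vol.origin, vol.axis_orientation)


def _wavelet_filters(wavelet_name: str):
    w = pywt.Wavelet(wavelet_name)
    # rescale by 1/sqrt(2) per axis so the undecimated analysis bank is
    # energy preserving (|L(w)|^2 + |H(w)|^2 = 1 for orthonormal pairs)
    lo = np.asarray(w.dec_lo, dtype=np.float64) / np.sqrt(2.0)
    hi = np.asarray(w.dec_hi, dtype=np.float64) / np.sqrt(2.0)
    return lo, hi


def wavelet_subbands(
    vol: VolumeGrid, wavelet_name: str = DEFAULT_WAVELET, boundary: str = "reflect"
) -> dict[str, VolumeGrid]:
    """Single-level undecimated separable 3-D wavelet transform.

    Every subband keeps the input shape so region masks apply directly.
    ``boundary`` is a scipy.ndimage mode; 'reflect' (default) pads
    symmetrically, 'wrap' gives the periodic transform under which the
    energy-preservation identity is exact.
    """
    lo, hi = _wavelet_filters(wavelet_name)
    flen = len(lo)
    for ax, n in enumerate(vol.shape):
        if n < flen:
            raise ImagingError(
                f"axis {ax} length {n} shorter than wavelet filter length {flen}"
            )
    out: dict[str, VolumeGrid] = {}
    # convolution along each axis; scipy.correlate1d with reversed taps
    lo_c, hi_c = lo[::-1], hi[::-1]
    for band in WAVELET_SUBBANDS:
        data = vol.data
        for axis, letter in enumerate(band):
            taps = lo_c if letter == "L" else hi_c
            data = ndimage.correlate1d(data, taps, axis=axis, mode=boundary)
        out[f"Wavelet-{band}"] = VolumeGrid(
            data, vol.spacing, vol.origin, vol.axis_orientation
        )
    return out


def build_image_set(
    vol: VolumeGrid,
    sigmas=DEFAULT_LOG_SIGMAS_MM,
    wavelet_name: str = DEFAULT_WAVELET,
) -> dict[str, VolumeGrid]:
    """Build the named, ordered derived-image set (13 with default sigmas).

    With a non-default ``sigmas`` list the set size changes; the feature
    catalogue validates the expected count downstream.
    """
    images: dict[str, VolumeGrid] = {"Intensities": vol}
    for s in sigmas:
        images[log_image_name(s)] = log_filter(vol, s)
    images.update(wavelet_subbands(vol, wavelet_name))
    return images
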