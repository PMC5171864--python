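"""Pixel-intensity densitometry of the mineralized area.

Alizarin-red fluorescence intensity within the mineralized area serves
as a proxy for mineral density or hemiray thickness: brighter pixels,
higher density.  Intensity is the luma (Y) channel of the YUV colour
model; the analysed spectrum is the integer range 15-254, and the low
(15-29) / high (30-44) intensity classes summarize the distribution for
group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import RegionMask

#: BT.601 luma weights, the YUV convention of common imaging software.
BT601 = (0.299, 0.587, 0.114)

SPECTRUM_MIN = 15
SPECTRUM_MAX = 254
LOW_CLASS = (15, 29)
HIGH_CLASS = (30, 44)


def rgb_to_luma(raster: np.ndarray, coefficients=BT601) -> np.ndarray:
    """Per-pixel luma Y = round(wr*R + wg*G + wb*B) as uint8."""
    img = np.asarray(raster, np.float64)
    wr, wg, wb = coefficients
    y = wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


@dataclass
class IntensityHistogram:
    """Relative frequency of each luma value in the 15-254 spectrum.

    ``freqs[i]`` is the relative frequency of luma value ``15 + i``
    (240 bins).  The default denominator is the number of masked pixels
    inside the spectrum (pixels below 15 or at 255 are excluded, which
    removes non-mineralized background); ``denominator='mask'`` divides
    by all masked pixels instead.
    """

    freqs: np.ndarray
    n_pixels_in_spectrum: int
    n_mask_pixels: int
    source_id: str = ""

    @property
    def empty(self) -> bool:
        return self.n_pixels_in_spectrum == 0

    @property
    def values(self) -> np.ndarray:
        """Luma values corresponding to ``freqs`` (15..254)."""
        return np.arange(SPECTRUM_MIN, SPECTRUM_MAX + 1)

    def frequency(self, value: int) -> float:
        """Relative frequency of one luma value."""
        if not SPECTRUM_MIN <= value <= SPECTRUM_MAX:
            return 0.0
        return float(self.freqs[value - SPECTRUM_MIN])


def histogram(
    luma: np.ndarray,
    mineral: RegionMask | np.ndarray,
    source_id: str = "",
    denominator: str = "spectrum",
) -> IntensityHistogram:
    """Intensity histogram of masked pixels within the 15-254 spectrum.

    An all-excluded input yields an empty-histogram signal
    (``n_pixels_in_spectrum == 0``, zero frequencies) rather than an error.
    """
    if denominator not in ("spectrum", "mask"):
        raise ValueError("denominator must be 'spectrum' or 'mask'")
    mask = mineral.mask if isinstance(mineral, RegionMask) else np.asarray(mineral, bool)
    y = np.asarray(luma)
    if y.shape != mask.shape:
        raise ValueError("luma and mask shapes differ")
    vals = y[mask].astype(int)
    n_mask = int(vals.size)
    in_spec = vals[(vals >= SPECTRUM_MIN) & (vals <= SPECTRUM_MAX)]
    counts = np.bincount(in_spec - SPECTRUM_MIN, minlength=240)[:240].astype(float)
    n_spec = int(in_spec.size)
    denom = n_spec if denominator == "spectrum" else n_mask
    freqs = counts / denom if denom > 0 else counts * 0.0
    return IntensityHistogram(freqs, n_spec, n_mask, source_id=source_id)


@dataclass(frozen=True)
class IntensityClasses:
    """Mass of the low (15-29) and high (30-44) intensity classes."""

    low_15_29: float
    high_30_44: float


def class_frequencies(h: IntensityHistogram) -> IntensityClasses:
    """Sum histogram mass over the low and high intensity classes."""
    lo = h.freqs[LOW_CLASS[0] - SPECTRUM_MIN : LOW_CLASS[1] - SPECTRUM_MIN + 1].sum()
    hi = h.freqs[HIGH_CLASS[0] - SPECTRUM_MIN : HIGH_CLASS[1] - SPECTRUM_MIN + 1].sum()
    return IntensityClasses(float(lo), float(hi))


def classes_from_luma_samples(samples: np.ndarray) -> IntensityClasses:
    """Intensity classes from a flat array of luma samples.

    Convenience for simulated records where pixel lumas are drawn
    directly rather than rendered into a raster.
    """
    arr = np.asarray(samples).reshape(1, -1)
    h = histogram(arr, np.ones_like(arr, bool))
    return class_frequencies(h)
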