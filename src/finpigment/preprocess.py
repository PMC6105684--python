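"""Grey-scale conversion and within-mask intensity normalisation.

Normalising each fin to zero mean and unit standard deviation over the fin
pixels removes differences in camera exposure and global illumination:
features computed downstream are invariant to any positive affine intensity
change of the raw image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalisedFin", "to_grey", "normalise", "PreprocessError"]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


class PreprocessError(ValueError):
    pass


@dataclass
class NormalisedFin:
    """Z-scored fin intensities.

    ``values`` is a float raster with NaN outside the mask so background
    pixels can never leak into a patch statistic.
    """

    values: np.ndarray
    mask: np.ndarray
    source_mean: float
    source_sd: float

    @property
    def fin_values(self) -> np.ndarray:
        """Flat array of the normalised intensities on fin pixels."""
        return self.values[self.mask]


def to_grey(pixels: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to luminance; grey input passes through.

    Uses BT.601 weights (0.299, 0.587, 0.114). Output is float64.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return pixels.astype(np.float64)
    if pixels.ndim == 3 and pixels.shape[2] == 3:
        return pixels.astype(np.float64) @ _LUMA
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        return pixels[..., :3].astype(np.float64) @ _LUMA
    raise PreprocessError(f"expected 1- or 3-channel raster, got shape {pixels.shape}")


def normalise(photo: np.ndarray, mask: np.ndarray) -> NormalisedFin:
    """Z-score grey intensities over the fin mask (population SD).

    Raises on a degenerate fin: fewer than two fin pixels, or zero intensity
    variance within the mask.
    """
    grey = np.asarray(photo, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if grey.shape != mask.shape:
        raise PreprocessError(f"image shape {grey.shape} != mask shape {mask.shape}")
    fin = grey[mask]
    if fin.size < 2:
        raise PreprocessError("mask has fewer than 2 fin pixels")
    m = float(fin.mean())
    s = float(fin.std())  # population convention (ddof=0)
    if s <= 0.0:
        raise PreprocessError("degenerate intensity: constant fin")
    values = np.full(grey.shape, np.nan)
    values[mask] = (fin - m) / s
    return NormalisedFin(values=values, mask=mask, source_mean=m, source_sd=s)
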