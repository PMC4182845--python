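"""Color-image loading, RGB→HSV conversion and saturation histograms.

Field photographs of mulched plots show very little contrast between dark
mulch film and moist soil in any single RGB plane; the saturation plane of
the HSV representation, by contrast, is clearly bimodal (soil is chromatic,
black mulch is nearly achromatic).  This module turns an 8-bit color
photograph into the quantized saturation histogram that every thresholding
method downstream consumes.

Conventions
-----------
* Channel values live on the [0, 1] scale after decoding 8-bit input
  (``value / 255``); thresholds are reported on the same scale.
* The saturation plane is quantized to 256 levels (bin ``k`` holds the
  gray value ``k / 255``) before histogram-based thresholding.  Binning
  uses round-half-to-even; boundary values are vanishingly rare in
  natural images, so any consistent rule suffices.
"""

from __future__ import annotations

import dataclasses
import os

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor

from .exceptions import InputError

N_LEVELS = 256
"""Number of gray levels of the quantized saturation plane."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RGBImage:
    """An m×n color raster with channel intensities in [0, 1].

    Parameters
    ----------
    pixels
        Array of shape ``(m, n, 3)``; red, green, blue in the last axis.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected an (m, n, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("image must have at least one pixel")
        if not np.isfinite(px).all():
            raise InputError("image contains non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """Image dimensions ``(m, n)`` = (rows, columns)."""
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class HSVImage:
    """Hue/saturation/value planes sharing the source image's dimensions.

    Hue lies in [0, 1); saturation and value in [0, 1].  An achromatic
    pixel (max channel = min channel) has saturation 0 by construction.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.saturation.shape


@dataclasses.dataclass(frozen=True)
class SaturationPlane:
    """The scalar image f(x, y) in [0, 1] that is actually thresholded."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise InputError(f"expected a 2-D array, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise InputError("plane contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise InputError("saturation values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def quantized(self) -> np.ndarray:
        """Integer bin indices ``round(s * 255)`` (round-half-to-even)."""
        return np.rint(self.values * (N_LEVELS - 1)).astype(np.intp)


@dataclasses.dataclass(frozen=True)
class GrayHistogram:
    """256-bin count vector over the quantized saturation plane.

    ``counts[k]`` is the number of pixels whose saturation falls in bin
    ``k``; ``bin_value(k) = k / 255`` recovers the gray value on [0, 1].
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_LEVELS,):
            raise InputError(f"expected {N_LEVELS} bins, got shape {c.shape}")
        if (c < 0).any():
            raise InputError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Bin probabilities p_k = counts_k / Σ counts."""
        total = self.counts.sum()
        if total == 0:
            raise InputError("empty histogram has no probabilities")
        return self.counts / total

    @property
    def levels(self) -> int:
        return N_LEVELS

    @staticmethod
    def bin_value(k: int | np.ndarray) -> float | np.ndarray:
        """Gray value of bin ``k`` on the [0, 1] scale."""
        return np.asarray(k) / (N_LEVELS - 1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def load_image(path: str | os.PathLike) -> RGBImage:
    """Read an 8-bit JPEG or PNG color photograph.

    An alpha channel, if present, is dropped; grayscale input is
    replicated across the three channels.  Intensities are rescaled
    to [0, 1] by dividing by 255.
    """
    raw = iio.imread(path)
    if raw.dtype != np.uint8:
        raise InputError(f"only 8-bit images are supported, got dtype {raw.dtype}")
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:
        raw = raw[..., :3]
    return RGBImage(raw.astype(np.float64) / 255.0)


def rgb_to_hsv(image: RGBImage) -> HSVImage:
    """Convert an RGB image to HSV planes.

    Standard conversion: V = max(R, G, B); S = (max − min) / max where
    max > 0 and 0 otherwise; H is the usual hexagonal hue in [0, 1).
    """
    hsv = skcolor.rgb2hsv(image.pixels)
    return HSVImage(hue=hsv[..., 0], saturation=hsv[..., 1], value=hsv[..., 2])


def hsv_to_rgb(hue: np.ndarray, saturation: np.ndarray, value: np.ndarray) -> RGBImage:
    """Inverse conversion, used by the synthetic-scene generator."""
    hsv = np.stack([hue, saturation, value], axis=-1)
    return RGBImage(np.clip(skcolor.hsv2rgb(hsv), 0.0, 1.0))


def extract_saturation(hsv: HSVImage) -> SaturationPlane:
    """Project out the saturation plane (unchanged)."""
    return SaturationPlane(hsv.saturation)


def saturation_histogram(plane: SaturationPlane) -> GrayHistogram:
    """Quantize the plane to 256 levels and count pixels per bin."""
    counts = np.bincount(plane.quantized().ravel(), minlength=N_LEVELS)
    return GrayHistogram(counts)
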