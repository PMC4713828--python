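"""Binarization of the subfoveal choroid into luminal and stromal pixels.

The processing chain mirrors the established ImageJ binarization protocol
for EDI-OCT choroid quantification: convert to 8-bit, optionally reduce
brightness, apply an auto local threshold (Niblack by default; Phansalkar
and Otsu variants available), and partition the ROI into dark (luminal,
vascular) and light (stromal, interstitial) pixels.

Threshold conventions
---------------------
* Niblack:      ``T(x) = mean_w(x) + k * std_w(x)`` over a square window of
  side ``2*radius + 1`` (k defaults to 0.2, the ImageJ plugin default).
* Phansalkar:   ``T(x) = m * (1 + p*exp(-q*m/255) + k*(s/R - 1))`` with
  p = 2, q = 10, R = 0.5 * 255, on the 8-bit scale.
* Window statistics use reflection (symmetric) padding at the image edge
  and are computed from exact integer integral images, so they agree
  bit-for-bit with a brute-force per-window loop.
* Tie rule: a pixel strictly below its threshold is luminal; a pixel equal
  to its threshold is stromal (constant regions are therefore stromal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.filters.rank import otsu as rank_otsu

from .oct_io import BScanImage
from .roi_geometry import SubfovealROI

METHODS = ("niblack", "phansalkar", "otsu_local", "otsu_global")

PHANSALKAR_P = 2.0
PHANSALKAR_Q = 10.0
PHANSALKAR_R = 0.5 * 255.0


@dataclass
class BinarizationParams:
    """Parameters of the auto-threshold step."""

    method: str = "niblack"
    radius: int = 15            # window half-width in pixels
    k: float = 0.2              # Niblack/Phansalkar coefficient
    brightness_offset: int = 0  # signed 8-bit units added before thresholding

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")


@dataclass
class PartitionMasks:
    """Exclusive, exhaustive partition of the ROI into luminal and stromal."""

    luminal: np.ndarray
    stromal: np.ndarray


def to_8bit(image: BScanImage) -> BScanImage:
    """Convert a B-scan to 8 bits.

    8-bit input is returned unchanged.  16-bit input is linearly rescaled
    by its own min-max to [0, 255] and rounded half-up; a constant 16-bit
    image maps to all zeros.
    """
    if image.bit_depth == 8:
        return image
    px = image.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px, dtype=np.uint8)
    else:
        out = np.floor((px - lo) * (255.0 / (hi - lo)) + 0.5).astype(np.uint8)
    return BScanImage(out, 8, image.lateral_scale, image.axial_scale, image.scan_id)


def adjust_brightness(image: BScanImage, offset: int) -> BScanImage:
    """Add a signed offset to every pixel, clamping to [0, 255]."""
    if image.bit_depth != 8:
        raise ValueError("brightness adjustment expects an 8-bit image; call to_8bit first")
    out = np.clip(image.pixels.astype(np.int16) + int(offset), 0, 255).astype(np.uint8)
    return BScanImage(out, 8, image.lateral_scale, image.axial_scale, image.scan_id)


def _window_stats(px: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact windowed mean and population std via integer integral images.

    Pads by reflection (symmetric), accumulates int64 sums of values and of
    squares — both exact for 8-bit data — then applies the one-pass
    variance formula.  Because the sums are exact integers, the result is
    bit-identical to an explicit per-window loop using the same formula.
    """
    w = 2 * radius + 1
    pad = np.pad(px.astype(np.int64), radius, mode="symmetric")
    n = w * w

    def winsum(a):
        ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.int64)
        ii[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
        return ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]

    s = winsum(pad)
    s2 = winsum(pad * pad)
    mean = s / n
    var = s2 / n - mean * mean
    std = np.sqrt(np.maximum(var, 0.0))
    return mean, std


def local_threshold(
    image: BScanImage,
    params: BinarizationParams,
    roi: SubfovealROI | None = None,
) -> np.ndarray:
    """Per-pixel threshold grid for the configured method.

    For ``otsu_global`` the single Otsu threshold is computed over the ROI
    pixels (over the whole image when no ROI is given) and broadcast.
    """
    if image.bit_depth != 8:
        raise ValueError("local thresholding expects an 8-bit image; call to_8bit first")
    px = image.pixels
    r = params.radius
    if params.method in ("niblack", "phansalkar", "otsu_local") and 2 * r + 1 > min(px.shape):
        raise ValueError(
            f"window radius {r} too large for a {px.shape[0]}x{px.shape[1]} image"
        )

    if params.method == "niblack":
        mean, std = _window_stats(px, r)
        return mean + params.k * std
    if params.method == "phansalkar":
        mean, std = _window_stats(px, r)
        return mean * (
            1.0
            + PHANSALKAR_P * np.exp(-PHANSALKAR_Q * mean / 255.0)
            + params.k * (std / PHANSALKAR_R - 1.0)
        )
    # Otsu on integer data returns the maximum of the lower (dark) class;
    # +0.5 places the threshold strictly between the classes so the strict
    # "below threshold -> luminal" rule assigns the dark class to lumen.
    if params.method == "otsu_local":
        fp = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        return rank_otsu(px, fp).astype(np.float64) + 0.5
    # otsu_global
    values = px[roi.mask] if roi is not None else px.ravel()
    if values.size == 0:
        return np.zeros_like(px, dtype=np.float64)
    if np.ptp(values) == 0:
        t = float(values.flat[0])  # degenerate: constant ROI stays stromal
    else:
        t = float(threshold_otsu(values)) + 0.5
    return np.full(px.shape, t, dtype=np.float64)


def partition_roi(
    image: BScanImage,
    roi: SubfovealROI,
    params: BinarizationParams,
) -> PartitionMasks:
    """Split ROI pixels into luminal (value < threshold) and stromal (>=).

    Applies the brightness offset from ``params`` before thresholding.
    Pixels outside the ROI are False in both masks; inside, the two masks
    are an exact partition.
    """
    if image.pixels.shape != roi.mask.shape:
        raise ValueError("image and ROI shapes do not match")
    img8 = adjust_brightness(to_8bit(image), params.brightness_offset)
    if roi.n_pixels == 0:
        empty = np.zeros_like(roi.mask)
        return PartitionMasks(luminal=empty, stromal=empty.copy())
    thr = local_threshold(img8, params, roi=roi)
    below = img8.pixels < thr
    return PartitionMasks(luminal=roi.mask & below, stromal=roi.mask & ~below)


def overlay_image(image: BScanImage, roi: SubfovealROI, masks: PartitionMasks) -> np.ndarray:
    """Debug overlay: luminal black, stromal white, non-ROI pixels untouched."""
    base = to_8bit(image).pixels.copy()
    base[masks.luminal] = 0
    base[masks.stromal] = 255
    return base
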