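"""Per-layer thickness, volume and intensity over a raster of B-scans.

Layers are bands between consecutive segmented boundaries: retina
(ILM to inner RPE border), RPE complex (inner to outer RPE border) and
choroid (outer RPE border to choroid-sclera junction).  Row ownership
matches the ROI convention — a band covers rows ``top < r <= bottom`` —
so the three bands tile the ILM-to-junction column exactly.

Volume integrates per-scan cross-sectional areas across the raster with
the trapezoidal rule at the stated inter-scan spacing.  Intensity is the
mean 8-bit pixel value inside the band divided by 255, i.e. a unitless
reflectivity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oct_io import BoundarySet, BScanImage, RasterSet

NAN = float("nan")

LAYER_BOUNDS = {
    "retina": ("ILM", "RPE_inner"),
    "RPE": ("RPE_inner", "RPE_outer"),
    "choroid": ("RPE_outer", "CSJ"),
}


@dataclass
class LayerMetrics:
    layer: str
    mean_thickness: float  # um
    volume: float          # mm^3
    mean_intensity: float  # unitless, [0, 1]
    eye_id: str = ""
    visit: str = ""


def layer_band(boundaries: BoundarySet, layer: str) -> tuple[np.ndarray, np.ndarray]:
    """(top, bottom) per-column boundary rows for a named layer."""
    try:
        top_name, bot_name = LAYER_BOUNDS[layer]
    except KeyError:
        raise ValueError(f"unknown layer {layer!r}; expected one of {sorted(LAYER_BOUNDS)}")
    return boundaries[top_name], boundaries[bot_name]


def thickness_profile(band: tuple[np.ndarray, np.ndarray], axial_scale: float) -> np.ndarray:
    """Per-column thickness (bottom - top) in um; NaN where undefined."""
    top, bottom = band
    return (bottom - top) * axial_scale


def _scan_area_um2(boundaries: BoundarySet, layer: str, image: BScanImage) -> float:
    """Cross-sectional area of one layer in one scan: sum of column thicknesses x lateral scale."""
    profile = thickness_profile(layer_band(boundaries, layer), image.axial_scale)
    return float(np.nansum(profile) * image.lateral_scale)


def layer_volume(raster: RasterSet, layer: str) -> float:
    """Trapezoidal volume of a layer across the raster, in mm^3."""
    areas = np.array([_scan_area_um2(bnd, layer, img) for img, bnd in raster.scans])
    return float(np.trapezoid(areas, dx=raster.inter_scan_spacing) * 1e-9)


def layer_intensity(image: BScanImage, band: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean 8-bit pixel value inside the band divided by 255 (NaN if empty)."""
    if image.bit_depth != 8:
        raise ValueError("layer intensity is defined on 8-bit images; call to_8bit first")
    top, bottom = band
    rows = np.arange(image.height)[:, None]
    with np.errstate(invalid="ignore"):
        mask = (rows > top[None, :]) & (rows <= bottom[None, :])
    if not mask.any():
        return NAN
    return float(image.pixels[mask].mean() / 255.0)


def compute_layer_metrics(
    raster: RasterSet,
    layers=("retina", "RPE", "choroid"),
) -> list[LayerMetrics]:
    """Thickness/volume/intensity per layer for one eye-visit raster.

    Mean thickness pools all defined columns of all scans; mean intensity
    pools all band pixels of all scans (8-bit conversion applied per scan).
    """
    from .binarization import to_8bit

    out = []
    for layer in layers:
        profiles, n_band, sum_band = [], 0, 0.0
        for img, bnd in raster.scans:
            profiles.append(thickness_profile(layer_band(bnd, layer), img.axial_scale))
            img8 = to_8bit(img)
            top, bottom = layer_band(bnd, layer)
            rows = np.arange(img8.height)[:, None]
            with np.errstate(invalid="ignore"):
                mask = (rows > top[None, :]) & (rows <= bottom[None, :])
            n_band += int(mask.sum())
            sum_band += float(img8.pixels[mask].sum())
        pooled = np.concatenate(profiles)
        out.append(LayerMetrics(
            layer=layer,
            mean_thickness=float(np.nanmean(pooled)) if np.isfinite(pooled).any() else NAN,
            volume=layer_volume(raster, layer),
            mean_intensity=(sum_band / n_band / 255.0) if n_band else NAN,
            eye_id=raster.eye_id, visit=raster.visit,
        ))
    return out
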