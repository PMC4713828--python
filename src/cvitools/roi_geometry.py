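"""Fovea localisation and the 1500 um subfoveal choroidal region.

The region of interest is the block of choroid beneath a horizontal line of
physical width ``width_um`` (default 1500 um) centred at the fovea, bounded
vertically by the outer RPE border above and the choroid-sclera junction
below.  Boundary-pixel ownership: a row belongs to the choroid when it lies
strictly below the outer RPE boundary and at-or-above the junction, i.e.
rows ``r`` with ``RPE_outer(c) < r <= CSJ(c)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .oct_io import BScanImage, BoundarySet

log = logging.getLogger(__name__)


@dataclass
class SubfovealROI:
    """Pixel mask of the subfoveal choroidal block plus its geometry."""

    fovea_x: int
    width_um: float
    col_start: int
    col_stop: int
    mask: np.ndarray
    rpe_outer: np.ndarray  # per-column row of the choroid's inner boundary
    csj: np.ndarray        # per-column row of the choroid's outer boundary

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def locate_fovea(boundaries: BoundarySet) -> int:
    """Column of the foveal centre.

    An explicit ``fovea_x`` stored with the boundaries wins.  Otherwise the
    fovea is taken as the column minimising inner retinal thickness
    (ILM to inner RPE border) — the foveal pit; ties break to the lowest
    column index.
    """
    if boundaries.fovea_x is not None:
        return int(boundaries.fovea_x)
    ilm = boundaries["ILM"]
    rpe_in = boundaries["RPE_inner"]
    defined = ~np.isnan(ilm) & ~np.isnan(rpe_in)
    if defined.sum() < 0.5 * boundaries.width:
        raise ValueError(
            "ILM/RPE_inner defined over less than half the scan; "
            "supply fovea_x explicitly in the boundary file"
        )
    thickness = np.where(defined, rpe_in - ilm, np.inf)
    return int(np.argmin(thickness))  # argmin returns the first (lowest) index on ties


def build_subfoveal_roi(
    image: BScanImage,
    boundaries: BoundarySet,
    fovea_x: int | None = None,
    width_um: float = 1500.0,
) -> SubfovealROI:
    """Construct the subfoveal choroidal ROI mask.

    The pixel window has width ``w = round(width_um / lateral_scale)``,
    split as ``floor(w/2)`` columns left of the fovea and the remainder to
    the right, clipped to the image.  If clipping removes more than 10% of
    the requested width a warning is logged and the clipped window is used.
    """
    boundaries.validate_against(image)
    if fovea_x is None:
        fovea_x = locate_fovea(boundaries)
    w = int(round(width_um / image.lateral_scale))
    col_start = fovea_x - w // 2
    col_stop = col_start + w
    clipped_start, clipped_stop = max(col_start, 0), min(col_stop, image.width)
    if w > 0 and (clipped_stop - clipped_start) < 0.9 * w:
        log.warning(
            "subfoveal window [%d, %d) clipped to [%d, %d); more than 10%% of the "
            "requested %g um width lies outside the scan",
            col_start, col_stop, clipped_start, clipped_stop, width_um,
        )
    col_start, col_stop = clipped_start, clipped_stop

    rpe_outer = boundaries["RPE_outer"]
    csj = boundaries["CSJ"]
    window = np.zeros(image.width, dtype=bool)
    window[col_start:col_stop] = True
    undefined = window & (np.isnan(rpe_outer) | np.isnan(csj))
    if undefined.any():
        raise ValueError(
            f"RPE_outer/CSJ undefined at column {int(np.flatnonzero(undefined)[0])} "
            "inside the subfoveal window"
        )

    rows = np.arange(image.height)[:, None]
    with np.errstate(invalid="ignore"):
        mask = (rows > rpe_outer[None, :]) & (rows <= csj[None, :]) & window[None, :]
    return SubfovealROI(
        fovea_x=int(fovea_x), width_um=float(width_um),
        col_start=col_start, col_stop=col_stop,
        mask=mask, rpe_outer=rpe_outer, csj=csj,
    )


def roi_area_mm2(roi: SubfovealROI, image: BScanImage) -> float:
    """Physical area of the ROI: pixel count x lateral x axial scale, in mm^2."""
    return roi.n_pixels * image.pixel_area_um2() * 1e-6
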