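"""Image, boundary and metric-table I/O with the package's unit conventions.

Conventions used throughout:

* pixel grids are ``(rows, columns)`` with row 0 at the top (vitreous side)
  and column 0 at the left; intervals are half-open ``[start, stop)``;
* physical scales are micrometres per pixel, supplied as metadata (they are
  never inferred from image content);
* layer boundaries are stored on disk as sparse polyline vertices and
  densified to one (float) row value per column at load time; columns
  outside a polyline's x-extent are undefined (NaN).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

BOUNDARY_NAMES = ("ILM", "RPE_inner", "RPE_outer", "CSJ")
"""Required boundaries, ordered top (inner retina) to bottom (outer choroid)."""

METRICS_HEADER = ["eye_id", "visit", "TCA_mm2", "LA_mm2", "SA_mm2", "CVI", "LA_SA", "SFCT_um"]
LAYERS_HEADER = ["eye_id", "visit", "layer", "mean_thickness_um", "volume_mm3", "mean_intensity"]


@dataclass
class BScanImage:
    """One OCT cross-section (B-scan) with its physical pixel scales.

    Parameters
    ----------
    pixels : ndarray
        2-D grayscale intensity grid, rows = axial depth, columns = lateral.
    bit_depth : int
        8 or 16.
    lateral_scale : float
        Micrometres per pixel along columns (> 0).
    axial_scale : float
        Micrometres per pixel along rows (> 0).
    scan_id : str
        Free-text identifier.
    """

    pixels: np.ndarray
    bit_depth: int
    lateral_scale: float
    axial_scale: float
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (self.lateral_scale > 0 and self.axial_scale > 0):
            raise ValueError(
                f"pixel scales must be positive, got lateral={self.lateral_scale}, "
                f"axial={self.axial_scale}"
            )
        vmax = 2 ** self.bit_depth - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise ValueError(f"pixel values outside [0, {vmax}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def pixel_area_um2(self) -> float:
        """Physical area of one (anisotropic) pixel in square micrometres."""
        return self.lateral_scale * self.axial_scale


@dataclass
class BoundarySet:
    """Per-column layer boundary rows for one B-scan.

    ``boundaries`` maps each name in :data:`BOUNDARY_NAMES` to a float array
    of length ``width`` giving the (sub-pixel) row of that boundary in each
    column; NaN marks columns where the boundary is undefined.
    """

    boundaries: dict[str, np.ndarray]
    scan_id: str = ""
    fovea_x: int | None = None
    lateral_scale: float | None = None
    axial_scale: float | None = None

    def __post_init__(self) -> None:
        widths = {len(v) for v in self.boundaries.values()}
        if len(widths) > 1:
            raise ValueError(f"boundary arrays have inconsistent widths: {sorted(widths)}")
        self.boundaries = {k: np.asarray(v, dtype=float) for k, v in self.boundaries.items()}
        self._check_ordering()

    def _check_ordering(self) -> None:
        """Anatomical ordering ILM <= RPE_inner <= RPE_outer <= CSJ wherever all defined."""
        if not all(n in self.boundaries for n in BOUNDARY_NAMES):
            return
        stack = np.vstack([self.boundaries[n] for n in BOUNDARY_NAMES])
        defined = ~np.isnan(stack).any(axis=0)
        diffs = np.diff(stack[:, defined], axis=0)
        if (diffs < 0).any():
            cols = np.flatnonzero(defined)[np.where(diffs < 0)[1]]
            pair = int(np.where(diffs < 0)[0][0])
            raise ValueError(
                f"boundary ordering violated at column {int(cols.min())}: "
                f"{BOUNDARY_NAMES[pair + 1]} lies above {BOUNDARY_NAMES[pair]}"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.boundaries[name]

    @property
    def width(self) -> int:
        return len(next(iter(self.boundaries.values())))

    def defined_columns(self, *names: str) -> np.ndarray:
        """Boolean column mask where every named boundary is defined."""
        names = names or BOUNDARY_NAMES
        mask = np.ones(self.width, dtype=bool)
        for n in names:
            mask &= ~np.isnan(self.boundaries[n])
        return mask

    def validate_against(self, image: BScanImage) -> None:
        if self.width != image.width:
            raise ValueError(
                f"boundary width {self.width} does not match image width {image.width}"
            )
        for name, rows in self.boundaries.items():
            finite = rows[~np.isnan(rows)]
            if finite.size and (finite.min() < 0 or finite.max() > image.height - 1):
                raise ValueError(f"boundary {name} leaves the image (height {image.height})")


@dataclass
class RasterSet:
    """Ordered (image, boundaries) pairs for one eye-visit raster volume."""

    scans: list[tuple[BScanImage, BoundarySet]]
    inter_scan_spacing: float  # um between adjacent B-scans
    eye_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        if self.inter_scan_spacing <= 0:
            raise ValueError("inter_scan_spacing must be positive")
        if len(self.scans) < 2:
            raise ValueError("a raster needs at least 2 scans")
        img0 = self.scans[0][0]
        for img, bnd in self.scans:
            if img.width != img0.width:
                raise ValueError("all scans in a raster must share the same width")
            if not (
                math.isclose(img.lateral_scale, img0.lateral_scale)
                and math.isclose(img.axial_scale, img0.axial_scale)
            ):
                raise ValueError("all scans in a raster must share identical pixel scales")
            bnd.validate_against(img)

    def __len__(self) -> int:
        return len(self.scans)


def read_bscan(path, lateral_scale: float, axial_scale: float, scan_id: str = "") -> BScanImage:
    """Read a PNG/TIFF B-scan and attach physical scales.

    RGB(A) inputs whose channels are identical are collapsed to one channel;
    genuinely coloured images are rejected.  Bit depth follows the stored
    dtype (uint8 -> 8, uint16 -> 16).
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise ValueError(f"{path}: RGB image with unequal channels is not a grayscale B-scan")
        arr = rgb[..., 0]
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    return BScanImage(arr, depth, lateral_scale, axial_scale, scan_id or str(path))


def _densify(polyline, width: int) -> np.ndarray:
    """Linearly interpolate polyline vertices to per-column rows (NaN outside)."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be a list of [x, row] pairs")
    order = np.argsort(pts[:, 0], kind="stable")
    pts = pts[order]
    cols = np.arange(width, dtype=float)
    rows = np.interp(cols, pts[:, 0], pts[:, 1])
    rows[(cols < pts[0, 0]) | (cols > pts[-1, 0])] = np.nan
    return rows


def read_boundaries(path, width: int | None = None) -> BoundarySet:
    """Read a boundary JSON file and densify its polylines to per-column rows.

    Schema::

        {"scan_id": str,
         "lateral_scale_um_per_px": float, "axial_scale_um_per_px": float,
         "fovea_x": int | null,
         "boundaries": {"ILM": [[x, row], ...], "RPE_inner": [...],
                        "RPE_outer": [...], "CSJ": [...]}}

    ``width`` defaults to one past the largest vertex x across boundaries.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "boundaries" not in doc:
        raise ValueError(f"{path}: missing 'boundaries' object")
    polys = doc["boundaries"]
    missing = [n for n in BOUNDARY_NAMES if n not in polys]
    if missing:
        raise ValueError(f"{path}: missing required boundary name(s): {', '.join(missing)}")
    if width is None:
        width = int(max(x for poly in polys.values() for x, _ in poly)) + 1
    dense = {name: _densify(polys[name], width) for name in polys}
    fov = doc.get("fovea_x")
    return BoundarySet(
        boundaries=dense,
        scan_id=doc.get("scan_id", str(path)),
        fovea_x=None if fov is None else int(fov),
        lateral_scale=doc.get("lateral_scale_um_per_px"),
        axial_scale=doc.get("axial_scale_um_per_px"),
    )


def write_boundaries(boundary_doc: dict, path) -> None:
    """Write a boundary document (polyline schema above) as JSON."""
    with open(path, "w") as fh:
        json.dump(boundary_doc, fh, indent=1)


def _fmt(x) -> str:
    if x is None:
        return ""
    x = float(x)
    if math.isnan(x):
        return ""
    return format(x, ".12g")


def write_metrics(rows, path) -> None:
    """Write ChoroidMetrics or LayerMetrics rows as CSV.

    Floats are rendered with 9 significant digits so a round-trip read
    reproduces them to well below 1e-9 relative error; missing values
    (undefined CVI or LA/SA) are written as empty fields.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty metrics table")
    kind = "choroid" if hasattr(rows[0], "TCA") else "layers"
    header = METRICS_HEADER if kind == "choroid" else LAYERS_HEADER
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(header)
        for r in rows:
            if kind == "choroid":
                wr.writerow([r.eye_id, r.visit, _fmt(r.TCA), _fmt(r.LA), _fmt(r.SA),
                             _fmt(r.CVI), _fmt(r.LA_SA), _fmt(r.SFCT)])
            else:
                wr.writerow([r.eye_id, r.visit, r.layer, _fmt(r.mean_thickness),
                             _fmt(r.volume), _fmt(r.mean_intensity)])


def read_metrics(path) -> list:
    """Read a metrics CSV written by :func:`write_metrics` back into rows."""
    from .choroid_metrics import ChoroidMetrics
    from .layer_metrics import LayerMetrics

    def val(s):
        return float(s) if s != "" else float("nan")

    with open(path, newline="") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        out = []
        if header == METRICS_HEADER:
            for row in rd:
                out.append(ChoroidMetrics(
                    eye_id=row[0], visit=row[1], TCA=val(row[2]), LA=val(row[3]),
                    SA=val(row[4]), CVI=val(row[5]), LA_SA=val(row[6]), SFCT=val(row[7]),
                ))
        elif header == LAYERS_HEADER:
            for row in rd:
                out.append(LayerMetrics(
                    eye_id=row[0], visit=row[1], layer=row[2],
                    mean_thickness=val(row[3]), volume=val(row[4]), mean_intensity=val(row[5]),
                ))
        else:
            raise ValueError(f"{path}: unrecognised metrics header {header}")
    return out
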