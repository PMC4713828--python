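"""Headline choroidal indices from a partitioned subfoveal ROI.

TCA is the physical area of the whole subfoveal choroidal block, LA the
area of its dark (luminal) pixels and SA of its light (stromal) pixels;
LA + SA = TCA by construction.  The choroidal vascularity index is the
luminal proportion, CVI = LA / TCA, stored as a proportion in [0, 1] and
conventionally reported as a percentage with one decimal.  SFCT is the
outer-RPE-to-junction distance at the foveal column; CT the mean of that
distance over the ROI columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .binarization import PartitionMasks
from .oct_io import BScanImage
from .roi_geometry import SubfovealROI

NAN = float("nan")


@dataclass
class ChoroidMetrics:
    """TCA/LA/SA/CVI/LA_SA/SFCT (+ mean CT) for one eye-visit.

    Areas in mm^2, thicknesses in um, CVI a proportion in [0, 1];
    undefined ratios (zero denominator) are NaN.
    """

    TCA: float
    LA: float
    SA: float
    CVI: float
    LA_SA: float
    SFCT: float
    CT: float = NAN
    eye_id: str = ""
    visit: str = ""

    @classmethod
    def from_areas(
        cls,
        la_mm2: float,
        sa_mm2: float | None = None,
        tca_mm2: float | None = None,
        sfct_um: float = NAN,
        **ids,
    ) -> "ChoroidMetrics":
        """Build the indices from printed areas (supply SA or TCA; LA + SA = TCA)."""
        if sa_mm2 is None and tca_mm2 is None:
            raise ValueError("supply sa_mm2 or tca_mm2 alongside la_mm2")
        if sa_mm2 is None:
            sa_mm2 = tca_mm2 - la_mm2
        if tca_mm2 is None:
            tca_mm2 = la_mm2 + sa_mm2
        cvi = la_mm2 / tca_mm2 if tca_mm2 > 0 else NAN
        la_sa = la_mm2 / sa_mm2 if sa_mm2 > 0 else NAN
        return cls(TCA=tca_mm2, LA=la_mm2, SA=sa_mm2, CVI=cvi, LA_SA=la_sa,
                   SFCT=sfct_um, **ids)

    @property
    def cvi_percent(self) -> float:
        return 100.0 * self.CVI


def compute_choroid_metrics(
    image: BScanImage,
    roi: SubfovealROI,
    masks: PartitionMasks,
    eye_id: str = "",
    visit: str = "",
) -> ChoroidMetrics:
    """Areas by pixel count x anisotropic pixel area; thicknesses from boundaries."""
    n_lum = int(masks.luminal.sum())
    n_str = int(masks.stromal.sum())
    if n_lum + n_str != roi.n_pixels:
        raise ValueError("masks do not partition the ROI")
    px_mm2 = image.pixel_area_um2() * 1e-6
    la, sa = n_lum * px_mm2, n_str * px_mm2
    tca = roi.n_pixels * px_mm2

    band = roi.csj - roi.rpe_outer
    sfct = float(band[roi.fovea_x] * image.axial_scale) if 0 <= roi.fovea_x < len(band) else NAN
    cols = slice(roi.col_start, roi.col_stop)
    ct = float(np.nanmean(band[cols]) * image.axial_scale) if roi.col_stop > roi.col_start else NAN

    if tca <= 0:
        warnings.warn("empty ROI: CVI undefined", stacklevel=2)
    # ratios from raw pixel counts: identical in value to the area ratios but
    # free of the scale factor's floating-point round-off
    return ChoroidMetrics(
        TCA=tca, LA=la, SA=sa,
        CVI=n_lum / roi.n_pixels if roi.n_pixels > 0 else NAN,
        LA_SA=n_lum / n_str if n_str > 0 else NAN,
        SFCT=max(sfct, 0.0) if sfct == sfct else NAN,
        CT=max(ct, 0.0) if ct == ct else NAN,
        eye_id=eye_id, visit=visit,
    )


def percent_change(baseline: float, followup: float) -> float:
    """Percent change from baseline: 100 * (baseline - followup) / baseline.

    Positive when the metric decreased at follow-up.  A zero baseline makes
    the change undefined (NaN, with a warning).
    """
    if baseline == 0:
        warnings.warn("percent change undefined for zero baseline", stacklevel=2)
        return NAN
    return 100.0 * (baseline - followup) / baseline


@dataclass
class PercentChange:
    """Per-eye percent changes of one metric with group summary and 95% CI."""

    metric: str
    values: np.ndarray = field(repr=False)
    mean: float = NAN
    sd: float = NAN
    ci_low: float = NAN
    ci_high: float = NAN


def percent_change_summary(metric: str, baselines, followups) -> PercentChange:
    """Per-eye percent changes plus mean, sample sd and a t-based 95% CI."""
    from scipy import stats

    b = np.asarray(baselines, dtype=float)
    f = np.asarray(followups, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up vectors must pair up")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = np.array([percent_change(bi, fi) for bi, fi in zip(b, f)])
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    mean = float(vals.mean()) if n else NAN
    sd = float(vals.std(ddof=1)) if n > 1 else NAN
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        lo = hi = NAN
    return PercentChange(metric=metric, values=vals, mean=mean, sd=sd, ci_low=lo, ci_high=hi)
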