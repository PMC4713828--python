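"""Ground-truth OCT phantoms: two-compartment choroid with known vascularity.

A phantom B-scan stacks, top to bottom, a dark vitreous, a retina band
with a Gaussian foveal pit in the inner surface, a bright RPE band, a
choroidal band of bright stroma with dark elliptical lumens, and a sclera.
Random ellipses (overlap allowed) are added to the choroidal band until
the union of lumen pixels reaches the requested luminal fraction, so the
generator knows the exact ground-truth lumen mask and achieved fraction.
Multiplicative unit-mean gamma noise emulates OCT speckle to first order
(no point-spread function, attenuation or shadowing).

All randomness flows from the spec's single integer seed; identical specs
produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .binarization import BinarizationParams, partition_roi
from .choroid_metrics import ChoroidMetrics, compute_choroid_metrics
from .oct_io import BoundarySet, BScanImage
from .roi_geometry import build_subfoveal_roi


@dataclass
class PhantomSpec:
    """Geometry, optics and target vascularity of one phantom B-scan.

    Default scales mimic a common spectral-domain OCT raster (11.6 um/px
    lateral, 3.87 um/px axial), and the default choroidal band height
    (~264 um) sits in the reported normal range.
    """

    width: int = 320
    height: int = 240
    lateral_scale: float = 11.6
    axial_scale: float = 3.87
    # boundary geometry (pixel rows; row 0 = top)
    ilm_row: float = 40.0
    pit_depth: float = 25.0       # foveal pit: ILM dips toward the RPE at centre
    pit_sigma: float = 18.0       # Gaussian pit half-width in columns
    rpe_inner_row: float = 130.0
    rpe_outer_row: float = 138.0
    choroid_thickness_px: float = 68.0
    csj_amplitude: float = 4.0    # sinusoidal undulation of the outer boundary
    # compartments (8-bit levels)
    vitreous_level: int = 15
    retina_level: int = 90
    rpe_level: int = 220
    stromal_level: int = 180
    luminal_level: int = 40
    sclera_level: int = 120
    # vascularity target
    f_true: float = 0.65
    lumen_radius_range: tuple[float, float] = (2.0, 5.0)
    speckle_variance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_true < 1.0:
            raise ValueError("f_true must lie strictly between 0 and 1")
        if self.luminal_level >= self.stromal_level:
            raise ValueError("luminal level must be darker than stromal level")
        if self.lumen_radius_range[0] <= 0:
            raise ValueError("lumen radii must be positive")


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    image: BScanImage
    boundaries: BoundarySet
    lumen_mask: np.ndarray
    achieved_fraction: float
    spec: PhantomSpec


def _boundary_rows(spec: PhantomSpec) -> dict[str, np.ndarray]:
    c = np.arange(spec.width, dtype=float)
    cx = spec.width // 2
    ilm = spec.ilm_row + spec.pit_depth * np.exp(-((c - cx) / spec.pit_sigma) ** 2 / 2.0)
    rpe_in = np.full(spec.width, spec.rpe_inner_row)
    rpe_out = np.full(spec.width, spec.rpe_outer_row)
    csj = (spec.rpe_outer_row + spec.choroid_thickness_px
           + spec.csj_amplitude * np.sin(2.0 * np.pi * c / spec.width))
    if (csj >= spec.height).any():
        raise ValueError("choroid-sclera junction leaves the image; reduce thickness or grow height")
    if (ilm >= rpe_in).any():
        raise ValueError("foveal pit reaches the RPE; reduce pit_depth")
    return {"ILM": ilm, "RPE_inner": rpe_in, "RPE_outer": rpe_out, "CSJ": csj}


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one phantom B-scan with ground-truth lumen mask.

    Ellipses are placed with centres uniform over the choroidal band and
    semi-axes uniform in ``lumen_radius_range`` until the union lumen
    fraction reaches ``f_true``; the generator raises if the fraction
    cannot be brought within 0.02 of the target (band too small for the
    smallest lumen).
    """
    rng = np.random.default_rng(spec.seed)
    rows_b = _boundary_rows(spec)
    H, W = spec.height, spec.width
    rows = np.arange(H, dtype=float)[:, None]

    def band_mask(top, bottom):
        return (rows > top[None, :]) & (rows <= bottom[None, :])

    band = band_mask(rows_b["RPE_outer"], rows_b["CSJ"])
    band_n = int(band.sum())
    min_area = np.pi * spec.lumen_radius_range[0] ** 2
    if band_n < 4 * min_area:
        raise ValueError("choroidal band too small for the smallest lumen")

    # paint compartments
    img = np.full((H, W), float(spec.sclera_level))
    img[rows <= rows_b["ILM"][None, :]] = spec.vitreous_level
    img[band_mask(rows_b["ILM"], rows_b["RPE_inner"])] = spec.retina_level
    img[band_mask(rows_b["RPE_inner"], rows_b["RPE_outer"])] = spec.rpe_level
    img[band] = spec.stromal_level

    # fill lumens until the union fraction reaches the target
    lumen = np.zeros((H, W), dtype=bool)
    band_rows, band_cols = np.nonzero(band)
    n_lum = 0
    rmin, rmax = spec.lumen_radius_range
    max_attempts = 50_000
    for _ in range(max_attempts):
        if n_lum / band_n >= spec.f_true:
            break
        i = rng.integers(len(band_rows))
        a, b = rng.uniform(rmin, rmax, size=2)
        theta = rng.uniform(0.0, np.pi)
        rr, cc = draw_ellipse(band_rows[i], band_cols[i], a, b,
                              shape=(H, W), rotation=theta)
        keep = band[rr, cc] & ~lumen[rr, cc]
        lumen[rr[keep], cc[keep]] = True
        n_lum += int(keep.sum())
    achieved = n_lum / band_n
    if abs(achieved - spec.f_true) > 0.02:
        raise RuntimeError(
            f"could not reach luminal fraction {spec.f_true:.3f} "
            f"(achieved {achieved:.3f} after {max_attempts} attempts)"
        )
    img[lumen] = spec.luminal_level

    if spec.speckle_variance > 0:
        v = spec.speckle_variance
        img = img * rng.gamma(shape=1.0 / v, scale=v, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    bset = BoundarySet(boundaries=rows_b, scan_id=f"phantom-{spec.seed}",
                       fovea_x=W // 2, lateral_scale=spec.lateral_scale,
                       axial_scale=spec.axial_scale)
    return PhantomTruth(
        image=BScanImage(img, 8, spec.lateral_scale, spec.axial_scale,
                         scan_id=f"phantom-{spec.seed}"),
        boundaries=bset, lumen_mask=lumen, achieved_fraction=achieved, spec=spec,
    )


def measure_cvi(
    truth: PhantomTruth,
    params: BinarizationParams | None = None,
    width_um: float = 1500.0,
) -> ChoroidMetrics:
    """Run the full ROI + binarization + metrics pipeline on a phantom."""
    params = params or BinarizationParams()
    roi = build_subfoveal_roi(truth.image, truth.boundaries, width_um=width_um)
    masks = partition_roi(truth.image, roi, params)
    return compute_choroid_metrics(truth.image, roi, masks)


def roi_true_fraction(truth: PhantomTruth, width_um: float = 1500.0) -> float:
    """Ground-truth luminal fraction restricted to the subfoveal ROI."""
    roi = build_subfoveal_roi(truth.image, truth.boundaries, width_um=width_um)
    if roi.n_pixels == 0:
        return float("nan")
    return float((truth.lumen_mask & roi.mask).sum() / roi.n_pixels)


def generate_cohort(
    n_eyes: int,
    f_baseline: float,
    f_followup: float,
    noise: float = 0.05,
    seed: int = 0,
    eye_sd: float = 0.047,
    change_sd: float = 0.028,
    spec: PhantomSpec | None = None,
) -> list[tuple[PhantomTruth, PhantomTruth]]:
    """Paired baseline/follow-up phantoms for ``n_eyes`` eyes.

    Per-eye baseline fractions are drawn N(f_baseline, eye_sd); the paired
    follow-up fraction subtracts a per-eye change drawn
    N(f_baseline - f_followup, change_sd).  Each eye keeps its geometry
    (choroidal thickness, boundaries) across visits; only the lumen fill
    and speckle differ, emulating a longitudinal re-scan of the same eye.
    """
    if not (0.0 < f_baseline < 1.0 and 0.0 < f_followup < 1.0):
        raise ValueError("group-mean fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    base = spec or PhantomSpec()
    pairs = []
    for _ in range(int(n_eyes)):
        thickness = float(np.clip(
            rng.normal(base.choroid_thickness_px, 8.0),
            40.0, base.height - base.rpe_outer_row - base.csj_amplitude - 2,
        ))
        f_b = float(np.clip(rng.normal(f_baseline, eye_sd), 0.10, 0.90))
        delta = rng.normal(f_baseline - f_followup, change_sd)
        f_f = float(np.clip(f_b - delta, 0.10, 0.90))
        seeds = rng.integers(2**31, size=2)
        eye_spec = replace(base, choroid_thickness_px=thickness,
                           speckle_variance=noise)
        pairs.append((
            generate_phantom(replace(eye_spec, f_true=f_b, seed=int(seeds[0]))),
            generate_phantom(replace(eye_spec, f_true=f_f, seed=int(seeds[1]))),
        ))
    return pairs
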