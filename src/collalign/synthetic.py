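"""Synthetic study generators: fiber fields, paired brightfield images,
IHC slides, and survival cohorts with known ground truth.

Every generator takes an explicit seed, draws all randomness from one
``numpy.random.Generator``, and returns the ground truth alongside the
rendered data so downstream stages can be validated end to end:

* :func:`make_fiber_image` emulates an SHG acquisition — bright fibers on a
  dark, noisy background — with each fiber's true axial angle recorded.
* :func:`make_he_pair` renders the same scene as an H&E brightfield image
  through a Beer-Lambert stain model and warps it by a known affine map,
  providing ground truth for registration recovery.
* :func:`make_ihc_image` renders DAB/hematoxylin tissue whose realized
  positive-pixel fraction is recorded exactly.
* :func:`make_cohort` simulates a surgical cohort with per-ROI alignment
  values, clinicopathological covariates, and exponential overall-survival
  times under a proportional-hazards effect of high collagen alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk, line_aa

from .fibers import Fiber, FiberSet, alignment_score
from .registration import AffineTransform, warp_image
from .stains import StainModel, compose_stains

__all__ = [
    "FiberFieldSpec",
    "CohortSpec",
    "HEPair",
    "IHCImage",
    "Cohort",
    "sample_axial_angles",
    "make_fiber_image",
    "make_he_pair",
    "make_ihc_image",
    "make_cohort",
]

# Tumor regions whose ROIs enter the patient-level alignment average.
TUMOR_REGIONS = ("low_grade", "high_grade", "core", "edge")


@dataclass(frozen=True)
class FiberFieldSpec:
    """Parameters of one synthetic fiber field.

    ``kappa`` is the concentration of the axial von Mises orientation
    distribution: 0 gives uniform axial angles, larger values concentrate
    fibers around ``mean_angle``; ``math.inf`` marks the degenerate case in
    which every fiber lies exactly at ``mean_angle``.
    """

    n_fibers: int = 300
    mean_angle: float = 90.0
    kappa: float = 2.0
    fiber_length_px: tuple[float, float] = (60.0, 15.0)  # mean, sd
    fiber_width_px: int = 2
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if min(self.image_size_px) < 64:
            raise ValueError("image dimensions must be >= 64")
        if not 0.0 <= self.mean_angle < 180.0:
            raise ValueError("mean_angle must lie in [0, 180)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0 (math.inf for degenerate)")
        if self.fiber_width_px < 1:
            raise ValueError("fiber_width_px must be >= 1")


def sample_axial_angles(
    n: int, mean_angle: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample axial orientations in degrees in [0, 180).

    Uses the standard axial-data construction: draw ``2*theta`` from a von
    Mises centered on ``2*mean_angle`` with concentration ``kappa``, then
    halve.  ``kappa=0`` yields uniform angles; ``kappa=inf`` is degenerate
    (all angles equal to the mean).
    """
    if math.isinf(kappa):
        return np.full(n, mean_angle % 180.0)
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(math.radians(2.0 * mean_angle), kappa, size=n)
    return (np.degrees(doubled) / 2.0) % 180.0


def _draw_segment(
    img: np.ndarray, x0: float, y0: float, x1: float, y1: float, width: int, amplitude: float
) -> None:
    """Accumulate an anti-aliased segment of the given width (max blend)."""
    h, w = img.shape
    theta = math.atan2(y1 - y0, x1 - x0)
    # unit normal for width offsets
    nx, ny = -math.sin(theta), math.cos(theta)
    for i in range(width):
        off = i - (width - 1) / 2.0
        r0 = int(round(y0 + off * ny))
        c0 = int(round(x0 + off * nx))
        r1 = int(round(y1 + off * ny))
        c1 = int(round(x1 + off * nx))
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] = np.maximum(img[rr, cc], amplitude * val)


def make_fiber_image(
    spec: FiberFieldSpec,
    *,
    amplitude: float = 200.0,
    noise_sigma: float = 3.0,
    poisson_noise: bool = False,
) -> tuple[np.ndarray, FiberSet]:
    """Render a fiber field and return it with its ground-truth FiberSet.

    The intensity image is float, background near zero with additive
    Gaussian noise (and optional Poisson shot noise on the signal); fibers
    are anti-aliased straight segments of amplitude ``amplitude``.  The
    returned FiberSet stores each drawn fiber's true axial angle, centroid,
    and length, so the field's true alignment is exactly
    ``alignment_score(fiber_set.angles_deg)``.
    """
    h, w = spec.image_size_px
    if h <= 0 or w <= 0:
        raise ValueError("zero-area image")
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((h, w), dtype=float)
    angles = sample_axial_angles(spec.n_fibers, spec.mean_angle, spec.kappa, rng)
    mean_len, sd_len = spec.fiber_length_px
    lengths = np.clip(rng.normal(mean_len, sd_len, size=spec.n_fibers), 8.0, None)
    cx = rng.uniform(0, w, size=spec.n_fibers)
    cy = rng.uniform(0, h, size=spec.n_fibers)
    fs = FiberSet(source_id=f"synthetic-seed{spec.seed}", pixel_size_um=spec.pixel_size_um)
    for i in range(spec.n_fibers):
        th = math.radians(angles[i])
        dx, dy = math.cos(th), math.sin(th)
        half = lengths[i] / 2.0
        _draw_segment(
            img,
            cx[i] - half * dx, cy[i] - half * dy,
            cx[i] + half * dx, cy[i] + half * dy,
            spec.fiber_width_px, amplitude,
        )
        fs.fibers.append(
            Fiber(centroid=(cx[i], cy[i]), theta_deg=float(angles[i]), length_px=float(lengths[i]))
        )
    if poisson_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, None), fs


@dataclass
class HEPair:
    """A synthetic H&E image paired with the SHG scene it was rendered from."""

    rgb: np.ndarray  # uint8 (H, W, 3)
    true_transform: AffineTransform  # H&E (moving) -> SHG (fixed)
    collagen_mask: np.ndarray  # boolean, in H&E coordinates
    stains: StainModel


def make_he_pair(
    shg: np.ndarray,
    fibers: FiberSet,
    transform: AffineTransform,
    stains: StainModel | None = None,
    seed: int = 0,
    *,
    n_nuclei: int = 120,
    collagen_od: float = 0.9,
    nucleus_od: float = 0.8,
) -> HEPair:
    """Render the H&E brightfield counterpart of an SHG scene.

    Collagen structures are placed in the eosin channel at the fiber
    locations (using the normalized SHG intensity as the eosin
    concentration) and random nuclear blobs in the hematoxylin channel; the
    channels are composed by the Beer-Lambert forward model and the scene
    is then resampled through ``transform`` so that a point ``p`` in the
    returned H&E image corresponds to ``transform(p)`` in the SHG frame.
    The true transform is carried in the result for recovery tests.
    """
    if stains is None:
        stains = StainModel.he()
    t = np.asarray(transform.A)
    if abs(np.linalg.det(t)) <= 1e-8:  # defensive; AffineTransform enforces this
        raise ValueError("transform must be invertible")
    rng = np.random.default_rng(seed)
    shg = np.asarray(shg, dtype=float)
    h, w = shg.shape
    peak = shg.max()
    eosin = collagen_od * (shg / peak if peak > 0 else shg)
    hema = np.zeros_like(shg)
    for _ in range(n_nuclei):
        r = rng.uniform(2.5, 5.0)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = disk((cy, cx), r, shape=(h, w))
        hema[rr, cc] = nucleus_od
    conc = np.stack([hema, eosin, np.zeros_like(shg)], axis=-1)
    # resample each concentration channel into the moving (H&E) frame:
    # he[p] = scene[T(p)]  <=>  warp by T^-1
    inv = transform.inverse()
    warped = np.stack(
        [warp_image(conc[..., i], inv, (h, w), cval=0.0) for i in range(3)], axis=-1
    )
    rgb = np.clip(compose_stains(warped, stains), 0, 255).astype(np.uint8)
    mask = warped[..., 1] > 0.25 * collagen_od
    return HEPair(rgb=rgb, true_transform=transform, collagen_mask=mask, stains=stains)


@dataclass
class IHCImage:
    """A synthetic DAB/hematoxylin IHC image with its exact positivity."""

    rgb: np.ndarray
    true_fraction: float
    n_dab: int
    n_hematoxylin: int


def make_ihc_image(
    target_positive_fraction: float,
    stains: StainModel | None = None,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    n_blobs: int = 60,
) -> IHCImage:
    """Render an IHC image whose DAB-positive pixel fraction is known exactly.

    Tissue is a union of random disks; among tissue pixels, exactly
    ``round(f * n)`` are assigned DAB stain and the rest hematoxylin, so the
    realized fraction under the positivity pixel rule is recorded without
    estimation error (up to 8-bit quantization when re-measured from RGB).
    """
    if not 0.0 <= target_positive_fraction <= 1.0:
        raise ValueError("target fraction must lie in [0, 1]")
    if stains is None:
        stains = StainModel.h_dab()
    rng = np.random.default_rng(seed)
    h, w = shape
    tissue = np.zeros((h, w), dtype=bool)
    for _ in range(n_blobs):
        rr, cc = disk((rng.uniform(0, h), rng.uniform(0, w)), rng.uniform(6, 16), shape=(h, w))
        tissue[rr, cc] = True
    idx = np.flatnonzero(tissue.ravel())
    rng.shuffle(idx)
    n_dab = int(round(target_positive_fraction * idx.size))
    dab_idx, hem_idx = idx[:n_dab], idx[n_dab:]
    dab = np.zeros(h * w)
    hem = np.zeros(h * w)
    dab[dab_idx] = rng.uniform(0.5, 0.9, size=dab_idx.size)
    hem[hem_idx] = rng.uniform(0.5, 0.9, size=hem_idx.size)
    conc = np.stack(
        [hem.reshape(h, w), dab.reshape(h, w), np.zeros((h, w))], axis=-1
    )
    rgb = np.clip(compose_stains(conc, stains), 0, 255).astype(np.uint8)
    n_hem = idx.size - n_dab
    frac = n_dab / idx.size if idx.size else float("nan")
    return IHCImage(rgb=rgb, true_fraction=frac, n_dab=n_dab, n_hematoxylin=n_hem)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation parameters for a surgical PDAC-like cohort.

    Defaults encode the study conditions of the modeled setting: 114
    patients, 12% with highly aligned stromal collagen (patient-level
    alignment >= 0.60), a hazard ratio of 2.25 for high vs low alignment,
    a 26.9-month baseline median overall survival, and ~40% censoring.
    """

    n_patients: int = 114
    frac_high: float = 0.12
    cutoff: float = 0.60
    log_hr_alignment: float = math.log(2.25)
    baseline_median_os_months: float = 26.9
    censor_fraction: float = 0.40
    covariate_effects: dict = field(default_factory=dict)  # name -> log HR
    alignment_range: tuple[float, float] = (0.289, 0.712)
    low_mean_sd: tuple[float, float] = (0.47, 0.07)
    high_mean_sd: tuple[float, float] = (0.635, 0.03)
    within_patient_sd: float = 0.04
    unknown_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_high <= 1.0:
            raise ValueError("frac_high must lie in [0, 1]")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.baseline_median_os_months <= 0:
            raise ValueError("baseline median must be positive")


# Bernoulli margins for the binary covariates, loosely matching the modeled
# cohort's characteristics (e.g. ~46% female, ~65% age > 65).
_COVARIATE_MARGINS = {
    "female": 53 / 114,
    "age_gt65": 74 / 114,
    "tumor_head": 103 / 114,
    "size_gt2cm": 89 / 113,
    "pT34": 80 / 113,
    "pN1": 81 / 114,
    "stage_late": 81 / 113,
    "grade_high": 83 / 106,
    "margin_r1": 28 / 114,
    "adjuvant": 69 / 114,
}


@dataclass
class Cohort:
    """Simulated cohort: one patients table, one per-ROI alignment table."""

    patients: pd.DataFrame
    rois: pd.DataFrame
    spec: CohortSpec

    def write_csv(self, patients_path, rois_path) -> None:
        self.patients.to_csv(patients_path, index=False)
        self.rois.to_csv(rois_path, index=False)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(8, 2 * (size - filled)))
        draw = draw[(draw >= lo) & (draw < hi)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def make_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort with ROI-level alignment and survival outcomes.

    Each patient receives 2-4 tumor-region cores (regions drawn from low
    grade / high grade / core / edge, 1-2 ROIs each) plus, usually, a
    normal-adjacent core; tumor-region ROI values are recentered so their
    mean equals the patient's drawn alignment exactly.  Overall survival is
    exponential with hazard ``h0 * exp(beta * 1[high] + sum covariate
    effects)`` where ``h0 = ln(2) / baseline_median``; censoring times are
    independent exponentials whose rate is solved so the expected censored
    fraction matches ``censor_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_high = int(round(spec.frac_high * n))
    high = np.zeros(n, dtype=bool)
    high[rng.choice(n, n_high, replace=False)] = True

    lo_lim, hi_lim = spec.alignment_range
    align = np.empty(n)
    align[~high] = _truncated_normal(
        rng, *spec.low_mean_sd, lo_lim, spec.cutoff, size=int((~high).sum())
    )
    align[high] = _truncated_normal(
        rng, *spec.high_mean_sd, spec.cutoff, hi_lim + 1e-9, size=n_high
    )

    cov = {}
    for name, p in _COVARIATE_MARGINS.items():
        x = (rng.random(n) < p).astype(float)
        if spec.unknown_rate > 0:
            x[rng.random(n) < spec.unknown_rate] = np.nan
        cov[name] = x

    h0 = math.log(2.0) / spec.baseline_median_os_months
    lin = spec.log_hr_alignment * high.astype(float)
    for name, beta in spec.covariate_effects.items():
        lin = lin + beta * np.nan_to_num(cov[name], nan=0.0)
    hazard = h0 * np.exp(lin)
    latent = rng.exponential(1.0 / hazard)
    if spec.censor_fraction > 0:
        # rate c with mean_i c/(c+h_i) = censor_fraction (exponential races)
        cf = spec.censor_fraction
        c = brentq(
            lambda c_: float(np.mean(c_ / (c_ + hazard))) - cf,
            1e-10, 1e4 * hazard.max(),
        )
        censor = rng.exponential(1.0 / c, size=n)
        event = (latent <= censor).astype(int)
        time = np.minimum(latent, censor)
    else:
        event = np.ones(n, dtype=int)
        time = latent
    time = np.maximum(time, 1e-3)

    roi_rows = []
    for i in range(n):
        n_tumor_cores = int(rng.integers(2, 5))
        regions = list(rng.choice(TUMOR_REGIONS, size=n_tumor_cores, replace=False))
        tumor_vals = []
        for ci, region in enumerate(regions):
            for ri in range(int(rng.integers(1, 3))):
                tumor_vals.append((f"P{i:03d}-C{ci}", region))
        vals = align[i] + rng.normal(0.0, spec.within_patient_sd, size=len(tumor_vals))
        vals = vals - vals.mean() + align[i]  # exact patient-level mean
        vals = np.clip(vals, 0.0, 1.0)
        for (core_id, region), v in zip(tumor_vals, vals):
            roi_rows.append(
                {"patient_id": f"P{i:03d}", "core_id": core_id, "region": region, "R": float(v)}
            )
        if rng.random() < 0.7:  # normal-adjacent core, excluded from aggregation
            for ri in range(int(rng.integers(1, 3))):
                roi_rows.append(
                    {
                        "patient_id": f"P{i:03d}",
                        "core_id": f"P{i:03d}-CN",
                        "region": "normal",
                        "R": float(np.clip(rng.normal(0.35, 0.05), 0.0, 1.0)),
                    }
                )

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "alignment_true": align,
            "high_true": high.astype(int),
            **cov,
            "os_months": time,
            "event": event,
        }
    )
    rois = pd.DataFrame(roi_rows)
    return Cohort(patients=patients, rois=rois, spec=spec)
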