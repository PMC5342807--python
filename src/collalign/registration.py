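"""Brightfield-to-SHG registration: stitching, collagen extraction from
color, mutual-information affine registration, and ROI transfer.

Registration follows the classic two-step recipe for multimodal histology:
(1) isolate collagenous stroma from the brightfield image by decorrelation
stretch plus K-means color clustering, so both images show the same
structure; (2) maximize mutual information between that collagen image and
the SHG image over a 6-parameter affine map, coarse-to-fine over a Gaussian
pyramid with a numerically estimated gradient and step-halving line search.

Coordinates are 0-based pixel (x right, y down); an :class:`AffineTransform`
maps moving-image coordinates into the fixed (SHG) frame.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.transform import rescale
from sklearn.cluster import KMeans

from .fibers import ROI
from .stains import StainModel, rgb_to_od

__all__ = [
    "AffineTransform",
    "StitchLayout",
    "RegistrationResult",
    "stitch_tiles",
    "decorrelation_stretch",
    "extract_collagen_mask",
    "mutual_information",
    "register_affine",
    "register_he_to_shg",
    "transfer_rois",
    "warp_image",
]


@dataclass(frozen=True)
class AffineTransform:
    """Planar affine map ``p_fixed = A @ p_moving + t`` on (x, y) columns."""

    A: np.ndarray  # (2, 2) linear part
    t: np.ndarray  # (2,) translation, pixels

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float).reshape(2, 2)
        t = np.asarray(self.t, dtype=float).reshape(2)
        if abs(np.linalg.det(a)) <= 1e-8:
            raise ValueError("linear part is (near-)singular")
        object.__setattr__(self, "A", a)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform":
        return cls(np.eye(2), np.array([tx, ty], float))

    @classmethod
    def rotation(cls, angle_deg: float, center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform":
        """Rotation about ``center`` by ``angle_deg`` (x-right / y-down frame)."""
        th = math.radians(angle_deg)
        a = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        c = np.asarray(center, float)
        return cls(a, c - a @ c)

    @classmethod
    def scaling(cls, sx: float, sy: float, center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform":
        a = np.diag([sx, sy]).astype(float)
        c = np.asarray(center, float)
        return cls(a, c - a @ c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) array of (x, y) points into the fixed frame."""
        return np.asarray(points, float) @ self.A.T + self.t

    def inverse(self) -> "AffineTransform":
        ai = np.linalg.inv(self.A)
        return AffineTransform(ai, -ai @ self.t)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``self after other`` (apply ``other`` first)."""
        return AffineTransform(self.A @ other.A, self.A @ other.t + self.t)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.A.ravel(), self.t])

    def to_json(self, path: str | Path, **metadata) -> None:
        d = {"matrix_2x3_row_major": np.column_stack([self.A, self.t]).tolist(), **metadata}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        m = np.asarray(d["matrix_2x3_row_major"], float)
        return cls(m[:, :2], m[:, 2])


@dataclass(frozen=True)
class StitchLayout:
    """Regular tile grid with fractional overlap between neighbors."""

    grid: tuple[int, int]  # (rows, cols)
    tile_size: tuple[int, int]  # (height, width)
    overlap: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 0.5:
            raise ValueError("overlap must lie in [0, 0.5)")

    @property
    def stride(self) -> tuple[int, int]:
        h, w = self.tile_size
        return (int(round(h * (1 - self.overlap))), int(round(w * (1 - self.overlap))))

    @property
    def composite_shape(self) -> tuple[int, int]:
        (r, c), (h, w), (sh, sw) = self.grid, self.tile_size, self.stride
        return (sh * (r - 1) + h, sw * (c - 1) + w)


def _feather_weights(tile_shape: tuple[int, int], margins: tuple[int, int]) -> np.ndarray:
    """Per-pixel blend weight: linear ramp over the overlap margin at each edge."""
    def ramp(n: int, m: int) -> np.ndarray:
        w = np.ones(n)
        if m > 0:
            edge = (np.arange(m) + 1.0) / (m + 1.0)
            w[:m] = np.minimum(w[:m], edge)
            w[-m:] = np.minimum(w[-m:], edge[::-1])
        return w
    return np.outer(ramp(tile_shape[0], margins[0]), ramp(tile_shape[1], margins[1]))


def stitch_tiles(tiles, layout: StitchLayout) -> np.ndarray:
    """Blend a grid of tiles into one composite using linear feathering.

    ``tiles`` is indexable as ``tiles[row][col]``; every tile must share
    ``layout.tile_size``.  Overlapping pixels are combined by a weighted
    average that ramps each tile's weight down toward its edges, so
    consistent overlaps reproduce the underlying scene exactly.
    """
    rows, cols = layout.grid
    th, tw = layout.tile_size
    sh, sw = layout.stride
    acc = np.zeros(layout.composite_shape, dtype=float)
    wacc = np.zeros_like(acc)
    weights = _feather_weights((th, tw), (th - sh, tw - sw))
    for r in range(rows):
        for c in range(cols):
            tile = np.asarray(tiles[r][c], dtype=float)
            if tile.shape != (th, tw):
                raise ValueError(f"tile ({r},{c}) has shape {tile.shape}, expected {(th, tw)}")
            ys, xs = r * sh, c * sw
            acc[ys:ys + th, xs:xs + tw] += tile * weights
            wacc[ys:ys + th, xs:xs + tw] += weights
    return acc / np.maximum(wacc, 1e-12)


def split_into_tiles(image: np.ndarray, layout: StitchLayout) -> list[list[np.ndarray]]:
    """Cut ``image`` into the overlapping tile grid described by ``layout``."""
    rows, cols = layout.grid
    th, tw = layout.tile_size
    sh, sw = layout.stride
    return [
        [image[r * sh:r * sh + th, c * sw:c * sw + tw].copy() for c in range(cols)]
        for r in range(rows)
    ]


def decorrelation_stretch(rgb: np.ndarray, *, clip: bool = True) -> np.ndarray:
    """Whiten the channel covariance and re-expand each channel to its
    original standard deviation, enhancing color separation.

    A (near-)constant image has degenerate covariance and is returned
    unchanged with a warning.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    flat = img.reshape(-1, 3)
    mu = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) < 1e-10:
        warnings.warn("degenerate channel covariance; decorrelation stretch skipped")
        return img.copy()
    whiten = evecs @ np.diag(evals ** -0.5) @ evecs.T
    sigma = flat.std(axis=0)
    out = (flat - mu) @ whiten * sigma + mu
    out = out.reshape(img.shape)
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return out


def extract_collagen_mask(
    rgb: np.ndarray,
    k: int = 4,
    reference_od: np.ndarray | None = None,
    seed: int = 0,
    *,
    max_fit_pixels: int = 50_000,
) -> np.ndarray:
    """Collagen mask by K-means color clustering of the stretched image.

    Pixels are clustered in the decorrelation-stretched color space; the
    returned mask is the cluster whose mean optical density is closest (by
    cosine distance) to ``reference_od`` — the eosin vector by default,
    since collagenous stroma is eosinophilic in H&E.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if reference_od is None:
        reference_od = StainModel.he().matrix[1]
    ref = np.asarray(reference_od, float)
    ref = ref / np.linalg.norm(ref)
    stretched = decorrelation_stretch(rgb)
    flat = stretched.reshape(-1, 3)
    rng = np.random.default_rng(seed)
    if flat.shape[0] > max_fit_pixels:
        fit_idx = rng.choice(flat.shape[0], max_fit_pixels, replace=False)
        fit = flat[fit_idx]
    else:
        fit = flat
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(fit)
    labels = km.predict(flat).reshape(rgb.shape[:2])
    od = rgb_to_od(np.asarray(rgb, float)).reshape(-1, 3)
    best, best_sim = 0, -np.inf
    for ci in range(k):
        sel = labels.ravel() == ci
        if not sel.any():
            continue
        mean_od = od[sel].mean(axis=0)
        norm = np.linalg.norm(mean_od)
        sim = -np.inf if norm < 1e-6 else float(mean_od @ ref) / norm
        if sim > best_sim:
            best, best_sim = ci, sim
    return labels == best


def _soft_joint_histogram(x: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    """Joint histogram with bilinear (tent-kernel) bin spreading.

    Each sample deposits weight into the 2x2 neighboring bins, making the
    histogram — and hence MI — continuous in sub-bin intensity changes.
    """
    def prep(v):
        lo, hi = v.min(), v.max()
        scale = (bins - 1) / (hi - lo) if hi > lo else 0.0
        s = (v - lo) * scale
        i0 = np.floor(s).astype(int)
        f = s - i0
        i0 = np.clip(i0, 0, bins - 2)
        return i0, np.clip(f, 0.0, 1.0)

    ix, fx = prep(x)
    iy, fy = prep(y)
    h = np.zeros((bins, bins))
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            np.add.at(h, (ix + dx, iy + dy), wx * wy)
    return h


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 32,
    sample_fraction: float = 1.0,
    seed: int = 0,
    *,
    smooth: bool = False,
) -> float:
    """Mutual information (bits) between two equally sized images.

    Computed from the joint histogram of a random sample of pixel pairs
    (``sample_fraction`` of all pixels; 1.0 uses every pixel).  With
    ``smooth=True`` the histogram uses linear bin spreading, the variant
    the registration optimizer ascends; the default hard binning makes
    MI(x, x) equal the histogram entropy of x exactly.
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.shape != bv.shape:
        raise ValueError("images must share dimensions")
    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n = max(1, int(round(sample_fraction * av.size)))
        idx = rng.choice(av.size, n, replace=False)
        av, bv = av[idx], bv[idx]
    if smooth:
        h = _soft_joint_histogram(av, bv, bins)
    else:
        h, _, _ = np.histogram2d(av, bv, bins=bins)
    p = h / h.sum()
    return _entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0)) - _entropy(p)


def warp_image(
    moving: np.ndarray,
    transform: AffineTransform,
    output_shape: tuple[int, int],
    *,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``moving`` into the fixed frame: out[p] = moving[T^-1 p]."""
    inv = transform.inverse()
    # (x, y) -> (row, col) conjugation
    swap = np.array([[0, 1], [1, 0]])
    m_rc = swap @ inv.A @ swap
    off_rc = inv.t[::-1]
    return ndimage.affine_transform(
        np.asarray(moving, float), m_rc, offset=off_rc,
        output_shape=output_shape, order=order, cval=cval, mode="constant",
    )


@dataclass
class RegistrationResult:
    """Outcome of :func:`register_affine`."""

    transform: AffineTransform
    mi: float
    mi_identity: float
    trace: list[list[float]] = field(default_factory=list)  # per-level MI iterates
    converged: bool = True
    warning: str | None = None


def _sample_mi(
    fixed: np.ndarray,
    moving: np.ndarray,
    w_params: np.ndarray,
    coords_xy: np.ndarray,
    fixed_vals: np.ndarray,
    bins: int,
) -> float:
    """MI objective for the fixed->moving map given by ``w_params``."""
    A = w_params[:4].reshape(2, 2)
    t = w_params[4:]
    pm = coords_xy @ A.T + t
    h, w = moving.shape
    ok = (pm[:, 0] >= 0) & (pm[:, 0] <= w - 1) & (pm[:, 1] >= 0) & (pm[:, 1] <= h - 1)
    if ok.sum() < 64:
        return -np.inf
    mv = ndimage.map_coordinates(moving, [pm[ok, 1], pm[ok, 0]], order=1, mode="nearest")
    hgram = _soft_joint_histogram(fixed_vals[ok], mv, bins)
    p = hgram / hgram.sum()
    return _entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0)) - _entropy(p)


def register_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    *,
    levels: int = 3,
    bins: int = 32,
    sample_fraction: float = 0.2,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
    init: AffineTransform | None = None,
    translation_search_px: float = 24.0,
    rotation_search_deg: float = 12.0,
) -> RegistrationResult:
    """Recover the affine map moving->fixed by maximizing mutual information.

    Coarse-to-fine over a factor-2 Gaussian pyramid (``levels`` deep).  At
    the coarsest level an exhaustive rotation x translation search (within
    ``rotation_search_deg`` and ``translation_search_px`` full-resolution
    pixels) seeds the optimizer; every level then maximizes the sampled MI
    over the 6 affine parameters with Powell's direction-set method in
    scaled coordinates (its per-direction line searches keep the MI trace
    monotone), up to ``max_iter`` function-free iterations per level or an
    MI gain below ``tol``.  If the final MI does not beat the identity map,
    the identity is returned with a warning flag.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.ndim != 2 or moving.ndim != 2:
        raise ValueError("register_affine expects 2-D images")
    if fixed.max() <= fixed.min() or moving.max() <= moving.min():
        raise ValueError("cannot register constant images")
    rng = np.random.default_rng(seed)

    # optimize the fixed->moving resampling map W; report its inverse
    w0 = (init.inverse() if init is not None else AffineTransform.identity()).params.copy()
    trace: list[float] = []
    # parameter scales: fractional change of the linear part vs whole pixels
    sig = np.array([0.005, 0.005, 0.005, 0.005, 1.0, 1.0])

    for level in range(levels - 1, -1, -1):
        s = 0.5 ** level
        if s < 1.0:
            f_l = rescale(fixed, s, anti_aliasing=True, preserve_range=True)
            m_l = rescale(moving, s, anti_aliasing=True, preserve_range=True)
        else:
            f_l, m_l = fixed, moving
        w_l = w0.copy()
        w_l[4:] *= s
        h, w = f_l.shape
        yy, xx = np.mgrid[0:h, 0:w]
        coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        vals = f_l.ravel()
        n = coords.shape[0]
        n_keep = max(256, int(round(sample_fraction * n)))
        if n_keep < n:
            idx = rng.choice(n, n_keep, replace=False)
            coords, vals = coords[idx], vals[idx]

        def mi_of(p: np.ndarray) -> float:
            return _sample_mi(f_l, m_l, p, coords, vals, bins)

        if level == levels - 1 and (translation_search_px > 0 or rotation_search_deg > 0):
            # brute-force rotation x translation seed at the coarsest level
            r = max(1, int(round(translation_search_px * s)))
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            angles = np.arange(-rotation_search_deg, rotation_search_deg + 1e-9, 3.0)
            if angles.size == 0:
                angles = np.array([0.0])
            best_p, best_v = w_l.copy(), mi_of(w_l)
            base_A = w_l[:4].reshape(2, 2)
            base_t = w_l[4:]
            for ang in angles:
                rot = AffineTransform.rotation(float(ang), center=(cx, cy))
                a_cand = base_A @ rot.A
                t_cand = base_A @ rot.t + base_t
                for dx in range(-r, r + 1, 2):
                    for dy in range(-r, r + 1, 2):
                        cand = np.concatenate([a_cand.ravel(), t_cand + [dx, dy]])
                        v = mi_of(cand)
                        if v > best_v:
                            best_p, best_v = cand, v
            w_l = best_p

        level_trace: list[float] = []

        def record(qk: np.ndarray) -> None:
            level_trace.append(mi_of(qk * sig))

        res = minimize(
            lambda q: -mi_of(q * sig),
            w_l / sig,
            method="Powell",
            callback=record,
            options={"xtol": 1e-3, "ftol": tol, "maxiter": max_iter},
        )
        w_l = res.x * sig
        trace.append(level_trace)
        w0 = w_l.copy()
        w0[4:] /= s

    w_final = AffineTransform(w0[:4].reshape(2, 2), w0[4:])
    # score at the finest level against identity
    h, w = fixed.shape
    yy, xx = np.mgrid[0:h, 0:w]
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    vals = fixed.ravel()
    n_keep = max(256, int(round(sample_fraction * coords.shape[0])))
    if n_keep < coords.shape[0]:
        idx = np.random.default_rng(seed + 1).choice(coords.shape[0], n_keep, replace=False)
        coords, vals = coords[idx], vals[idx]
    mi_final = _sample_mi(fixed, moving, w_final.params, coords, vals, bins)
    mi_ident = _sample_mi(fixed, moving, AffineTransform.identity().params, coords, vals, bins)
    if mi_final < mi_ident:
        return RegistrationResult(
            AffineTransform.identity(), mi_ident, mi_ident, trace,
            converged=False, warning="optimizer failed to improve on identity",
        )
    return RegistrationResult(w_final.inverse(), mi_final, mi_ident, trace)


def register_he_to_shg(
    he_rgb: np.ndarray,
    shg: np.ndarray,
    *,
    k: int = 4,
    reference_od: np.ndarray | None = None,
    seed: int = 0,
    **register_kwargs,
) -> RegistrationResult:
    """Two-step brightfield-to-SHG registration.

    Extracts the collagen mask from the H&E image (decorrelation stretch +
    K-means color clustering), then registers that mask to the SHG image
    with :func:`register_affine`.  The returned transform maps H&E (moving)
    coordinates into the SHG (fixed) frame.
    """
    mask = extract_collagen_mask(he_rgb, k=k, reference_od=reference_od, seed=seed)
    smooth_mask = ndimage.gaussian_filter(mask.astype(float), 1.0)
    return register_affine(shg, smooth_mask, seed=seed, **register_kwargs)


def transfer_rois(
    rois: list[ROI],
    transform: AffineTransform,
    target_shape: tuple[int, int] | None = None,
) -> list[ROI]:
    """Map ROIs through an affine transform into the fixed frame.

    Each ROI's four corners are mapped and an axis-aligned square is
    re-imposed on the resulting bounding box (side = mean of the box
    dimensions, which preserves the side length under rigid maps).  ROIs
    extending beyond ``target_shape`` are clipped and flagged.
    """
    out = []
    for roi in rois:
        corners = np.array(
            [
                [roi.x, roi.y],
                [roi.x + roi.side_px, roi.y],
                [roi.x, roi.y + roi.side_px],
                [roi.x + roi.side_px, roi.y + roi.side_px],
            ],
            dtype=float,
        )
        mapped = transform.apply(corners)
        lo = mapped.min(axis=0)
        hi = mapped.max(axis=0)
        side = int(round((hi - lo).mean()))
        x, y = int(round(lo[0])), int(round(lo[1]))
        clipped = False
        if target_shape is not None:
            h, w = target_shape
            nx, ny = max(0, x), max(0, y)
            side_x = min(x + side, w) - nx
            side_y = min(y + side, h) - ny
            nside = max(0, min(side_x, side_y))
            clipped = (nx, ny, nside) != (x, y, side)
            x, y, side = nx, ny, nside
        out.append(ROI(x=x, y=y, side_px=side, region=roi.region, roi_id=roi.roi_id, clipped=clipped))
    return out
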