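"""Fiber extraction from SHG-style images and the collagen alignment statistic.

Fiber orientations are *axial*: a fiber at angle theta is indistinguishable
from one at theta + 180 deg.  The alignment statistic is therefore the
circular mean resultant length computed on doubled angles, which maps the
axial identification onto the full circle.  R spans 0 (isotropic) to 1
(perfectly parallel field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "Fiber",
    "FiberSet",
    "ROI",
    "AlignmentResult",
    "alignment_score",
    "extract_fibers",
    "roi_alignment",
]


@dataclass(frozen=True)
class Fiber:
    """A single extracted fiber segment.

    Parameters
    ----------
    centroid : (x, y) in pixel coordinates, 0-based, x right / y down.
    theta_deg : axial orientation in [0, 180), measured from the +x axis
        toward +y (i.e. image-down), in degrees.
    length_px : arc length of the segment in pixels; strictly positive.
    """

    centroid: tuple[float, float]
    theta_deg: float
    length_px: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg < 180.0:
            object.__setattr__(self, "theta_deg", float(self.theta_deg) % 180.0)
        if self.length_px <= 0:
            raise ValueError("fiber length must be positive")


@dataclass
class FiberSet:
    """A collection of fibers extracted from (or drawn into) one image."""

    fibers: list[Fiber] = field(default_factory=list)
    source_id: str = ""
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.fibers)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([f.theta_deg for f in self.fibers], dtype=float)

    @property
    def lengths_px(self) -> np.ndarray:
        return np.array([f.length_px for f in self.fibers], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": [f.centroid[0] for f in self.fibers],
                "y": [f.centroid[1] for f in self.fibers],
                "theta_deg": [f.theta_deg for f in self.fibers],
                "length_px": [f.length_px for f in self.fibers],
            }
        )


@dataclass(frozen=True)
class ROI:
    """Square region of interest; 400 um side at the native pixel size.

    Half-open pixel extent [x, x + side) x [y, y + side), 0-based.
    """

    x: int
    y: int
    side_px: int
    region: str = "core"
    roi_id: str = ""
    clipped: bool = False

    @classmethod
    def from_physical(
        cls, x: int, y: int, pixel_size_um: float, side_um: float = 400.0, **kw
    ) -> "ROI":
        return cls(x=x, y=y, side_px=int(round(side_um / pixel_size_um)), **kw)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.side_px), slice(self.x, self.x + self.side_px)

    def contains(self, px: float, py: float) -> bool:
        return self.x <= px < self.x + self.side_px and self.y <= py < self.y + self.side_px


@dataclass(frozen=True)
class AlignmentResult:
    """Mean resultant length for one ROI; ``defined`` is False when no fibers."""

    R: float
    n_fibers: int
    roi_id: str = ""
    region: str = ""
    defined: bool = True


def alignment_score(
    angles_deg: Sequence[float] | np.ndarray,
    *,
    weights: Sequence[float] | None = None,
    axial: bool = True,
) -> float:
    """Mean resultant vector length of a set of fiber orientations.

    With ``axial=True`` (default) angles are doubled before the vector sum,
    the standard correction for orientation (mod-180) data: R = 1 for a
    perfectly parallel field and R = 0 for, e.g., {0, 90} degrees.  With
    ``weights`` each angle contributes proportionally (length weighting);
    otherwise each fiber counts once.

    Raises
    ------
    ValueError
        If ``angles_deg`` is empty.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("alignment_score requires at least one angle")
    # center on the first angle before converting: R is rotation-invariant,
    # and centering makes degenerate (all-identical) inputs exactly 1.0
    rad = np.deg2rad((a - a.flat[0]) * (2.0 if axial else 1.0))
    if weights is None:
        c = np.cos(rad).mean()
        s = np.sin(rad).mean()
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
        wsum = w.sum()
        if wsum <= 0:
            raise ValueError("weights must have positive sum")
        c = float(np.cos(rad) @ w) / wsum
        s = float(np.sin(rad) @ w) / wsum
    return float(math.hypot(c, s))


def _segment_paths(skeleton: np.ndarray) -> list[np.ndarray]:
    """Split a skeleton into simple paths by deleting branch points.

    Returns a list of (n, 2) arrays of (row, col) coordinates, one per
    connected component of the branch-point-free skeleton.
    """
    neighbor_kernel = np.ones((3, 3), dtype=int)
    neighbor_kernel[1, 1] = 0
    nb = ndimage.convolve(skeleton.astype(int), neighbor_kernel, mode="constant")
    branch = skeleton & (nb >= 3)
    pruned = skeleton & ~branch
    labels, n = ndimage.label(pruned, structure=np.ones((3, 3), dtype=int))
    paths: list[np.ndarray] = []
    if n:
        coords = np.argwhere(labels > 0)
        lab = labels[coords[:, 0], coords[:, 1]]
        order = np.argsort(lab, kind="stable")
        coords, lab = coords[order], lab[order]
        splits = np.searchsorted(lab, np.arange(2, n + 1))
        paths = np.split(coords, splits)
    return [p for p in paths if len(p) >= 2]


def _path_orientation_deg(coords: np.ndarray) -> float:
    """Axial orientation of a pixel path from the principal axis of its
    coordinates, in degrees in [0, 180) measured from +x toward +y."""
    xy = np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)
    xy -= xy.mean(axis=0)
    # principal eigenvector of the 2x2 scatter matrix
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    theta = math.degrees(math.atan2(v[1], v[0]))
    return theta % 180.0


def _path_length(coords: np.ndarray) -> float:
    """Arc length of a skeleton path: count steps weighting diagonals sqrt(2).

    Pixels are not ordered along the path, so the length is estimated from
    the number of pixels and the path's extent along its principal axis.
    """
    xy = np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)
    xy -= xy.mean(axis=0)
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    proj = xy @ v
    return float(proj.max() - proj.min()) + 1.0


def extract_fibers(
    image: np.ndarray,
    *,
    min_length_px: float = 30.0,
    smoothing_scale: float = 1.5,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    source_id: str = "",
    pixel_size_um: float = 1.0,
) -> FiberSet:
    """Segment bright curvilinear structures and return them as fibers.

    Pipeline: Gaussian smooth -> threshold (Otsu by default, or a fixed
    value) -> skeletonize -> delete branch points to split the skeleton into
    simple paths -> per-path orientation from the principal axis of the
    pixel coordinates.  Paths shorter than ``min_length_px`` are discarded.
    A blank image yields an empty FiberSet, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("extract_fibers expects a 2-D single-channel image")
    if img.size == 0:
        raise ValueError("empty image")
    fs = FiberSet(source_id=source_id, pixel_size_um=pixel_size_um)
    if img.max() <= img.min():
        return fs
    sm = gaussian(img, sigma=smoothing_scale, preserve_range=True)
    if threshold_method == "otsu":
        thr = threshold_otsu(sm)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_method='fixed' requires threshold_value")
        thr = threshold_value
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    fg = sm > thr
    if not fg.any():
        return fs
    skel = skeletonize(fg)
    for coords in _segment_paths(skel):
        length = _path_length(coords)
        if length < min_length_px:
            continue
        theta = _path_orientation_deg(coords)
        cy, cx = coords.mean(axis=0)
        fs.fibers.append(Fiber(centroid=(float(cx), float(cy)), theta_deg=theta, length_px=length))
    return fs


def roi_alignment(
    image: np.ndarray,
    roi: ROI,
    *,
    min_length_px: float = 30.0,
    smoothing_scale: float = 1.5,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    length_weighted: bool = False,
) -> AlignmentResult:
    """Crop an ROI, extract fibers, and score alignment.

    Fibers belong to the ROI by construction (extraction runs on the crop).
    An ROI over blank tissue returns a flagged-undefined result; an ROI
    extending outside the image raises.
    """
    h, w = image.shape[:2]
    if roi.x < 0 or roi.y < 0 or roi.x + roi.side_px > w or roi.y + roi.side_px > h:
        raise ValueError(f"ROI {roi.roi_id or (roi.x, roi.y)} lies outside the image")
    crop = np.asarray(image)[roi.slices()]
    fs = extract_fibers(
        crop,
        min_length_px=min_length_px,
        smoothing_scale=smoothing_scale,
        threshold_method=threshold_method,
        threshold_value=threshold_value,
    )
    if len(fs) == 0:
        return AlignmentResult(R=float("nan"), n_fibers=0, roi_id=roi.roi_id,
                               region=roi.region, defined=False)
    weights = fs.lengths_px if length_weighted else None
    r = alignment_score(fs.angles_deg, weights=weights)
    return AlignmentResult(R=r, n_fibers=len(fs), roi_id=roi.roi_id, region=roi.region)
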