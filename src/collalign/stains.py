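"""Optical-density conversion, color deconvolution, and IHC scoring.

The Beer-Lambert model expresses a brightfield pixel as
``I = I0 * 10**(-c . V)`` where ``V`` stacks unit optical-density (OD)
vectors, one row per stain, and ``c`` holds per-stain concentrations.
Deconvolution inverts that mixture per pixel: ``c = OD @ inv(V)``.
Positivity of a DAB-stained slide is then the pixel count ratio
DAB / (DAB + hematoxylin), background excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StainModel",
    "PositivityResult",
    "rgb_to_od",
    "od_to_rgb",
    "color_deconvolve",
    "compose_stains",
    "positivity_fraction",
    "stromal_score",
    "average_scores",
    "emt_double_positive_fraction",
]

# Ruifrok-Johnston OD vectors, the de-facto standard basis for H&E and H-DAB.
_H = (0.650, 0.704, 0.286)
_E = (0.072, 0.990, 0.105)
_DAB = (0.268, 0.570, 0.776)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainModel:
    """3x3 matrix of unit OD vectors; rows are stains, columns RGB channels."""

    matrix: np.ndarray
    names: tuple[str, str, str] = ("stain1", "stain2", "stain3")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        m = np.stack([_unit(row) for row in m])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def he(cls) -> "StainModel":
        """Hematoxylin / eosin / orthogonal residual."""
        resid = _unit(np.cross(_H, _E))
        return cls(np.array([_H, _E, resid]), names=("hematoxylin", "eosin", "residual"))

    @classmethod
    def h_dab(cls) -> "StainModel":
        """Hematoxylin / DAB / orthogonal residual."""
        resid = _unit(np.cross(_H, _DAB))
        return cls(np.array([_H, _DAB, resid]), names=("hematoxylin", "dab", "residual"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.matrix.tolist(), "names": list(self.names)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainModel":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["matrix"]), names=tuple(d["names"]))


def rgb_to_od(rgb: np.ndarray, background_intensity: float | np.ndarray = 255.0) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    OD = -log10(max(I, 1) / I0); zero intensities are clamped to 1 so the
    OD stays finite.  ``background_intensity`` may be scalar or per-channel.
    """
    i0 = np.asarray(background_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("background intensity must be positive")
    img = np.maximum(np.asarray(rgb, dtype=float), 1.0)
    return -np.log10(img / i0)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (float output, not quantized)."""
    return background_intensity * np.power(10.0, -np.asarray(od, dtype=float))


def compose_stains(
    concentrations: np.ndarray, stains: StainModel, background_intensity: float = 255.0
) -> np.ndarray:
    """Beer-Lambert forward model: concentration maps -> float RGB image.

    ``concentrations`` has shape (H, W, 3), one channel per stain row.
    """
    c = np.asarray(concentrations, dtype=float)
    od = c @ stains.matrix
    return od_to_rgb(od, background_intensity)


def color_deconvolve(
    od: np.ndarray, stains: StainModel, *, clip_negative: bool = True
) -> tuple[np.ndarray, int]:
    """Unmix an OD image into per-stain concentration maps.

    Returns ``(concentrations, n_clipped)`` where concentrations has shape
    (H, W, 3) ordered as the stain rows, and ``n_clipped`` counts pixels in
    which any negative concentration was clipped to zero.
    """
    od = np.asarray(od, dtype=float)
    conc = od @ stains.inverse
    n_clipped = 0
    if clip_negative:
        neg = conc < 0
        n_clipped = int(np.any(neg, axis=-1).sum())
        conc = np.where(neg, 0.0, conc)
    return conc, n_clipped


@dataclass(frozen=True)
class PositivityResult:
    """DAB positivity of one ROI: fraction = n_dab / (n_dab + n_hematoxylin)."""

    fraction: float
    n_dab: int
    n_hematoxylin: int
    n_background: int
    od_threshold: float
    defined: bool = True


def positivity_fraction(
    dab: np.ndarray, hematoxylin: np.ndarray, od_threshold: float = 0.15
) -> PositivityResult:
    """Classify pixels as DAB, hematoxylin, or background and score positivity.

    A pixel is DAB when its DAB concentration reaches the threshold and
    exceeds hematoxylin; hematoxylin when its concentration reaches the
    threshold and is >= DAB; anything else is background and excluded.
    With no stained pixels the fraction is flagged undefined.
    """
    d = np.asarray(dab, dtype=float)
    h = np.asarray(hematoxylin, dtype=float)
    if d.shape != h.shape:
        raise ValueError("stain maps must share dimensions")
    is_dab = (d >= od_threshold) & (d > h)
    is_hem = (h >= od_threshold) & (h >= d)
    n_dab = int(is_dab.sum())
    n_hem = int(is_hem.sum())
    n_bg = int(d.size - n_dab - n_hem)
    if n_dab + n_hem == 0:
        return PositivityResult(float("nan"), 0, 0, n_bg, od_threshold, defined=False)
    return PositivityResult(n_dab / (n_dab + n_hem), n_dab, n_hem, n_bg, od_threshold)


def stromal_score(fraction: float) -> int:
    """Ordinal stromal positivity: 1 negative/low (<10%), 2 moderate
    (10-50%, boundaries inclusive), 3 high (>50%)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction < 0.10:
        return 1
    if fraction <= 0.50:
        return 2
    return 3


def average_scores(scores: list[float]) -> float:
    """Mean of independent reviewer scores (e.g. two blinded observers)."""
    if not scores:
        raise ValueError("no scores to average")
    return float(np.mean(scores))


def emt_double_positive_fraction(
    cells: pd.DataFrame,
    thr1: float,
    thr2: float,
    *,
    marker1: str = "ecadherin",
    marker2: str = "vimentin",
    epithelial_col: str = "epithelial",
) -> float:
    """Fraction of epithelial cells co-expressing both markers.

    ``cells`` is a per-cell table with intensity columns for the two markers
    and a boolean epithelial flag; only epithelial cells enter the
    denominator.
    """
    epi = cells[cells[epithelial_col].astype(bool)]
    if len(epi) == 0:
        raise ValueError("no epithelial cells in table")
    pos = (epi[marker1] >= thr1) & (epi[marker2] >= thr2)
    return float(pos.mean())
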