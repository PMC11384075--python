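"""Affine landmark registration between stain images and spatial coordinates.

The fiducial circles are visible both in the stained tissue photograph and
in the reconstructed barcode density, so a handful of manually picked
landmark pairs determines a 2-D affine transform (6 parameters: rotation,
anisotropic scale, shear, translation) mapping image pixels to global nm.
The fit is linear least squares; at least 3 non-collinear pairs are
required for a unique solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AffineTransform",
    "LandmarkPair",
    "DegenerateLandmarksError",
    "fit_affine",
    "apply_affine",
    "read_landmarks",
    "write_transform",
    "read_transform",
]


class DegenerateLandmarksError(ValueError):
    pass


@dataclass(frozen=True)
class AffineTransform:
    """2x3 coefficient matrix mapping (x, y, 1) -> (x', y')."""

    matrix: tuple[tuple[float, float, float], tuple[float, float, float]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def linear(self) -> np.ndarray:
        return self.as_array()[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.as_array()[:, 2]

    @property
    def is_degenerate(self) -> bool:
        return abs(float(np.linalg.det(self.linear))) < 1e-12

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "AffineTransform":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (2, 3) or not np.isfinite(arr).all():
            raise ValueError(f"affine matrix must be finite 2x3, got {arr!r}")
        return cls(tuple(tuple(float(v) for v in row) for row in arr))


@dataclass(frozen=True)
class LandmarkPair:
    """source (image pixels) -> target (global nm) correspondence."""

    src_x: float
    src_y: float
    dst_x: float
    dst_y: float


def fit_affine(pairs: list[LandmarkPair]) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine fit; returns the transform and per-pair residuals.

    Minimizes sum ||A [src, 1] - dst||^2.  Raises
    :class:`DegenerateLandmarksError` for fewer than 3 pairs or (near-)
    collinear sources, where the fit is not unique.
    """
    if len(pairs) < 3:
        raise DegenerateLandmarksError(f"need >= 3 landmark pairs, got {len(pairs)}")
    src = np.array([[p.src_x, p.src_y] for p in pairs], dtype=float)
    dst = np.array([[p.dst_x, p.dst_y] for p in pairs], dtype=float)
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise DegenerateLandmarksError("non-finite landmark coordinates")
    design = np.hstack([src, np.ones((len(pairs), 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise DegenerateLandmarksError("landmark sources are collinear")
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    transform = AffineTransform.from_array(coeffs.T)
    residuals = np.linalg.norm(design @ coeffs - dst, axis=1)
    return transform, residuals


def apply_affine(t: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Apply the transform to an (n, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ t.linear.T + t.translation
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# small text formats


def read_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Tab-separated ``src_x src_y dst_x dst_y`` rows; '#' lines ignored."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = [float(v) for v in line.split("\t")]
        if len(vals) != 4:
            raise ValueError(f"landmark row needs 4 columns, got {len(vals)}: {line!r}")
        pairs.append(LandmarkPair(*vals))
    return pairs


def write_transform(t: AffineTransform, path: str | Path) -> None:
    arr = t.as_array()
    with open(path, "w") as fh:
        fh.write("#affine 2x3, row-major: a11 a12 tx / a21 a22 ty\n")
        for row in arr:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_transform(path: str | Path) -> AffineTransform:
    rows = [
        [float(v) for v in line.split("\t")]
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return AffineTransform.from_array(np.asarray(rows))
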