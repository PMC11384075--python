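"""Fiducial-circle detection on barcode-density images.

Fiducial markers are physical concentric-circle marks on the flow cell.
They carry no nano-wells, so they appear as voids in the per-tile barcode
occupancy.  Each tile's occupancy is binned into a coarse density image
(default 25 raw units per pixel), inverted so voids become bright, denoised
with non-local means, binarized, and searched with a circle Hough transform
at two radius ranges — outer circles (40-80 px) and inner circles
(15-30 px).  When all expected circles of a tile are found, their joint
centroid anchors the tile for stitching; tiles with missing circles get a
centroid interpolated from grid-adjacent tiles (fiducial placement within a
tile is constant across the flow cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from skimage.restoration import denoise_nl_means
from skimage.transform import hough_circle

from .hdmi_index import TileIndex, decompose_tile_id

__all__ = [
    "DensityImage",
    "Circle",
    "TileFiducials",
    "FiducialParams",
    "EmptyImageError",
    "build_density_image",
    "preprocess_image",
    "detect_circles",
    "detect_tile_fiducials",
    "tile_centroid",
    "interpolate_missing",
]


class EmptyImageError(ValueError):
    """Raised when a density image is requested for an empty tile."""


@dataclass(frozen=True)
class FiducialParams:
    """Detection parameters.

    ``denoise_h`` is the non-local-means filtering strength on the 0-255
    intensity scale; ``threshold`` the binarization cut after inversion and
    denoising.  Radius ranges are in binned pixels.  ``min_center_distance``
    (defaulting to twice the largest outer radius) suppresses duplicate
    detections of the same marker; ``vote_threshold`` is the minimum
    normalized circle-transform response accepted as a detection.
    """

    bin_size: int = 25
    denoise_h: float = 100.0
    threshold: int = 128
    outer_radius_range: tuple[int, int] = (40, 80)
    inner_radius_range: tuple[int, int] = (15, 30)
    radius_step: int = 2
    n_fiducials: int = 4
    min_center_distance: float | None = None
    vote_threshold: float = 0.45
    patch_size: int = 5
    patch_distance: int = 6

    def center_distance(self, radius_range: tuple[int, int]) -> float:
        """Suppression radius around an accepted center.

        Defaults to the largest radius of the range searched: duplicate
        responses of one marker fall within its own radius, while distinct
        markers sit further apart than that.
        """
        if self.min_center_distance is not None:
            return self.min_center_distance
        return float(radius_range[1])


@dataclass
class DensityImage:
    """Binned barcode occupancy, max-normalized to the 0-255 range.

    ``data[i, j]`` covers raw coordinates ``x in [origin_x + j*b, ...+b)``,
    ``y in [origin_y + i*b, ...+b)`` with ``b = bin_size``.
    """

    data: np.ndarray  # uint8, (rows, cols)
    bin_size: int
    origin: tuple[float, float] = (0.0, 0.0)
    tile_id: int | None = None


@dataclass(frozen=True)
class Circle:
    x: float  # center column, px
    y: float  # center row, px
    radius: float  # px
    kind: str  # "outer" | "inner"
    score: float = 0.0


@dataclass
class TileFiducials:
    tile_id: int
    circles: list[Circle] = field(default_factory=list)
    centroid: tuple[float, float] | None = None  # raw units, tile-local
    complete: bool = False
    outer_mean: tuple[float, float] | None = None  # raw units
    inner_mean: tuple[float, float] | None = None
    interpolated: bool = False


def build_density_image(index: TileIndex, bin_size: int = 25) -> DensityImage:
    """Bin valid-barcode positions into a max-normalized occupancy image.

    The image spans whole bins from the origin up to the largest occupied
    bin on each axis.
    """
    if len(index) == 0:
        raise EmptyImageError(f"tile {index.tile_id} has no records")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    x = index.x.astype(np.int64)
    y = index.y.astype(np.int64)
    j = x // bin_size
    i = y // bin_size
    cols = int(j.max()) + 1
    rows = int(i.max()) + 1
    counts = np.bincount(i * cols + j, minlength=rows * cols).reshape(rows, cols)
    peak = counts.max()
    data = np.round(counts * (255.0 / peak)).astype(np.uint8) if peak else counts.astype(np.uint8)
    return DensityImage(data=data, bin_size=bin_size, tile_id=index.tile_id)


def preprocess_image(img: DensityImage, params: FiducialParams | None = None) -> np.ndarray:
    """Invert (voids become bright), denoise, binarize to {0, 255}."""
    params = params or FiducialParams()
    inverted = (255 - img.data.astype(np.float64))
    denoised = denoise_nl_means(
        inverted,
        h=params.denoise_h,
        patch_size=params.patch_size,
        patch_distance=params.patch_distance,
        fast_mode=True,
        preserve_range=True,
    )
    return np.where(denoised >= params.threshold, 255, 0).astype(np.uint8)


def _detect_range(
    binary: np.ndarray,
    radius_range: tuple[int, int],
    kind: str,
    params: FiducialParams,
    max_circles: int,
) -> list[Circle]:
    rmin, rmax = radius_range
    radii = np.arange(rmin, rmax + 1, params.radius_step)
    accum = hough_circle(binary, radii)  # (n_radii, H, W), normalized responses
    best = accum.max(axis=0)
    best_r = radii[accum.argmax(axis=0)]

    circles: list[Circle] = []
    work = best.copy()
    h, w = work.shape
    d = params.center_distance(radius_range)
    for _ in range(max_circles):
        flat = int(work.argmax())
        i, j = divmod(flat, w)
        score = float(work[i, j])
        if score < params.vote_threshold:
            break
        # Thick rings and filled disks admit a plateau of near-maximal
        # responses around the true center; argmax lands on the plateau's
        # corner, so take the center of mass of the plateau instead.
        i0, i1 = max(0, int(i - d)), min(h, int(i + d) + 1)
        j0, j1 = max(0, int(j - d)), min(w, int(j + d) + 1)
        patch = best[i0:i1, j0:j1]
        plateau = patch >= score - 0.02
        ii, jj = np.nonzero(plateau)
        cy = float(ii.mean()) + i0
        cx = float(jj.mean()) + j0
        circles.append(Circle(x=cx, y=cy, radius=float(best_r[i, j]), kind=kind, score=score))
        i0, i1 = max(0, int(i - d)), min(h, int(i + d) + 1)
        j0, j1 = max(0, int(j - d)), min(w, int(j + d) + 1)
        work[i0:i1, j0:j1] = -1.0
    return circles


def detect_circles(
    binary: np.ndarray, params: FiducialParams | None = None, max_per_range: int | None = None
) -> list[Circle]:
    """Run the circle transform once per radius range on a binary void image.

    The bright void pattern itself is the evidence image: a marker's ring
    (outer) and filled disk boundary (inner) both produce full-perimeter
    responses at their radius.  Detections closer than the minimum center
    distance are merged (the concentric inner/outer pair of one marker is
    resolved by running the two radius ranges separately).
    """
    params = params or FiducialParams()
    k = max_per_range if max_per_range is not None else params.n_fiducials
    out = _detect_range(binary, params.outer_radius_range, "outer", params, k)
    inner = _detect_range(binary, params.inner_radius_range, "inner", params, k)
    return out + inner


def tile_centroid(fiducials: TileFiducials, bin_size: int, origin: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
    """Arithmetic mean of all detected circle centers, in raw units.

    Pixel centers map back to raw units at the pixel midpoint
    (``(px + 0.5) * bin_size``).
    """
    if not fiducials.circles:
        raise ValueError(f"tile {fiducials.tile_id} has no circles")
    cx = float(np.mean([c.x for c in fiducials.circles]))
    cy = float(np.mean([c.y for c in fiducials.circles]))
    return ((cx + 0.5) * bin_size + origin[0], (cy + 0.5) * bin_size + origin[1])


def _class_mean(circles: list[Circle], kind: str, bin_size: int) -> tuple[float, float] | None:
    pts = [(c.x, c.y) for c in circles if c.kind == kind]
    if not pts:
        return None
    arr = np.asarray(pts)
    return (
        (float(arr[:, 0].mean()) + 0.5) * bin_size,
        (float(arr[:, 1].mean()) + 0.5) * bin_size,
    )


def detect_tile_fiducials(index: TileIndex, params: FiducialParams | None = None) -> TileFiducials:
    """Full per-tile pipeline: density image, preprocessing, circle detection.

    ``complete`` requires ``n_fiducials`` circles in each radius class (the
    2 * n_fiducials circles of the concentric markers); the centroid is the
    combined mean of all of them and is only set for complete tiles.
    """
    params = params or FiducialParams()
    fid = TileFiducials(tile_id=index.tile_id)
    try:
        img = build_density_image(index, params.bin_size)
    except EmptyImageError:
        return fid
    binary = preprocess_image(img, params)
    fid.circles = detect_circles(binary, params)
    n_out = sum(c.kind == "outer" for c in fid.circles)
    n_in = sum(c.kind == "inner" for c in fid.circles)
    fid.complete = n_out == params.n_fiducials and n_in == params.n_fiducials
    fid.outer_mean = _class_mean(fid.circles, "outer", params.bin_size)
    fid.inner_mean = _class_mean(fid.circles, "inner", params.bin_size)
    if fid.complete:
        fid.centroid = tile_centroid(fid, params.bin_size)
    return fid


def interpolate_missing(
    fiducials: Mapping[int, TileFiducials],
) -> tuple[dict[int, TileFiducials], list[int]]:
    """Fill missing tile centroids from grid-adjacent tiles.

    Fiducial placement within a tile is constant across the flow cell, so a
    missing tile-local centroid is estimated as the mean of the available
    centroids of neighbors at grid distance 1 (same swath, adjacent row, or
    adjacent swath, same row).  Returns the completed mapping and the ids of
    tiles that stay unresolved (no neighbor with a centroid).
    """
    grid = {}
    for tid in fiducials:
        surface, swath, row = decompose_tile_id(tid)
        grid[(surface, swath, row)] = tid

    out = {tid: fid for tid, fid in fiducials.items()}
    unresolved: list[int] = []
    for tid, fid in fiducials.items():
        if fid.centroid is not None:
            continue
        surface, swath, row = decompose_tile_id(tid)
        neighbor_pts = []
        for ds, dr in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            n_tid = grid.get((surface, swath + ds, row + dr))
            if n_tid is None:
                continue
            n_fid = fiducials[n_tid]
            if n_fid.centroid is not None:
                neighbor_pts.append(n_fid.centroid)
        if not neighbor_pts:
            unresolved.append(tid)
            continue
        arr = np.asarray(neighbor_pts, dtype=float)
        patched = TileFiducials(
            tile_id=tid,
            circles=list(fid.circles),
            centroid=(float(arr[:, 0].mean()), float(arr[:, 1].mean())),
            complete=fid.complete,
            outer_mean=fid.outer_mean,
            inner_mean=fid.inner_mean,
            interpolated=True,
        )
        out[tid] = patched
    return out, unresolved


def write_fiducial_report(
    fiducials: Mapping[int, TileFiducials], path: str | Path
) -> None:
    """Tab-separated per-tile report (centroid, completeness, circle count)."""
    with open(path, "w") as fh:
        fh.write("#tile_id\tn_circles\tcomplete\tinterpolated\tcentroid_x\tcentroid_y\n")
        for tid in sorted(fiducials):
            f = fiducials[tid]
            cx, cy = f.centroid if f.centroid is not None else (float("nan"), float("nan"))
            fh.write(
                f"{tid}\t{len(f.circles)}\t{int(f.complete)}\t{int(f.interpolated)}\t{cx:.2f}\t{cy:.2f}\n"
            )


def save_debug_images(img: DensityImage, binary: np.ndarray, out_dir: str | Path) -> None:
    """Optional grayscale PNG dumps of the density and binarized images."""
    from skimage.io import imsave

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    imsave(out_dir / f"tile_{img.tile_id}_density.png", img.data, check_contrast=False)
    imsave(out_dir / f"tile_{img.tile_id}_binary.png", binary.astype(np.uint8), check_contrast=False)
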