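"""Tile stitching: from per-tile read coordinates to one physical frame.

Read-name coordinates are local to the sequencer's imaging tiles.  The
fiducial markers sit on a regular physical grid (their spacing is known
from microscopy), so each tile's detected fiducial centroid tells us where
that tile's frame sits on the chip.  Stitching is translation-only per
tile: offset = expected grid position of the centroid minus its observed
local position.  A least-squares scale calibration converts raw units to
nm.  Swaths 1/3/5 start at the same tile-row position; swaths 2/4/6 are
staggered by one tile.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fiducial_detect import TileFiducials
from .hdmi_index import (
    IndexFormatError,
    TileIndex,
    decompose_tile_id,
    pack_barcodes,
    unpack_barcodes,
)

__all__ = [
    "ScaleCalibration",
    "TileOffset",
    "GlobalIndex",
    "StitchError",
    "calibrate_scale",
    "expected_centroid",
    "compute_tile_offsets",
    "apply_offsets",
    "write_global_index",
    "read_global_index",
]


class StitchError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleCalibration:
    """nm per raw coordinate unit, fitted from measured fiducial spacings.

    ``source`` holds the (nm, raw_units) spacing pairs the fit used; with
    several pairs the scale is the least-squares slope through the origin.
    """

    nm_per_unit: float
    source: tuple[tuple[float, float], ...] = ()

    def to_nm(self, units: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(units, dtype=float) * self.nm_per_unit

    def to_units(self, nm: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(nm, dtype=float) / self.nm_per_unit


@dataclass(frozen=True)
class TileOffset:
    tile_id: int
    dx: float  # raw units added to local x
    dy: float


def calibrate_scale(spacings: Sequence[tuple[float, float]]) -> ScaleCalibration:
    """Fit nm-per-unit from (nm, raw_unit) spacing pairs.

    Minimizes sum of (nm - k * raw)^2, i.e. k = sum(nm*raw) / sum(raw^2).
    """
    if not spacings:
        raise StitchError("at least one (nm, raw_units) spacing pair is required")
    nm = np.asarray([p[0] for p in spacings], dtype=float)
    raw = np.asarray([p[1] for p in spacings], dtype=float)
    if np.any(raw == 0):
        raise StitchError("zero raw-unit spacing in calibration pairs")
    k = float((nm * raw).sum() / (raw * raw).sum())
    if k <= 0:
        raise StitchError(f"non-positive calibrated scale {k}")
    return ScaleCalibration(nm_per_unit=k, source=tuple((float(a), float(b)) for a, b in spacings))


def expected_centroid(
    row: int,
    col: int,
    swath: int,
    spacing: tuple[float, float],
    anchor: tuple[float, float],
    offset_axis: str = "y",
) -> tuple[float, float]:
    """Expected global position (raw units) of a tile's fiducial centroid.

    ``row``/``col`` are zero-based grid indices (col = swath - 1 in the
    single-surface case); the anchor is the top-left tile's centroid.
    Even-numbered swaths are staggered by one tile spacing along
    ``offset_axis``.
    """
    if not 1 <= swath <= 6:
        raise StitchError(f"swath must be in 1..6, got {swath}")
    sx, sy = spacing
    x = anchor[0] + col * sx
    y = anchor[1] + row * sy
    if swath % 2 == 0:
        if offset_axis == "y":
            y += sy
        else:
            x += sx
    return x, y


def compute_tile_offsets(
    fiducials: Mapping[int, TileFiducials],
    spacing: tuple[float, float],
    anchor: tuple[float, float] | None = None,
    offset_axis: str = "y",
) -> tuple[dict[int, TileOffset], list[int]]:
    """Per-tile translation placing each fiducial centroid on the expected grid.

    ``spacing`` is the inter-tile fiducial spacing in raw units (from the
    scale calibration or chip layout).  The anchor defaults to the observed
    centroid of the top-left tile (lowest swath, lowest row), so that tile
    gets offset (0, 0) when its centroid matches expectation.  Tiles with no
    centroid (detection and interpolation both failed) are excluded and
    returned in the second element.
    """
    excluded = [tid for tid, f in fiducials.items() if f.centroid is None]
    usable = {tid: f for tid, f in fiducials.items() if f.centroid is not None}
    if not usable:
        raise StitchError("no tile has a usable fiducial centroid")

    def grid_pos(tid: int) -> tuple[int, int, int]:
        _, swath, row = decompose_tile_id(tid)
        return row - 1, swath - 1, swath

    if anchor is None:
        top_left = min(usable, key=lambda t: (grid_pos(t)[1], grid_pos(t)[0]))
        r0, c0, s0 = grid_pos(top_left)
        cen = usable[top_left].centroid
        # anchor = would-be centroid of grid cell (0, 0) in swath-1 phase
        exp = expected_centroid(r0, c0, s0, spacing, (0.0, 0.0), offset_axis)
        anchor = (cen[0] - exp[0], cen[1] - exp[1])

    offsets: dict[int, TileOffset] = {}
    for tid, f in usable.items():
        r, c, s = grid_pos(tid)
        ex, ey = expected_centroid(r, c, s, spacing, anchor, offset_axis)
        ox, oy = f.centroid
        offsets[tid] = TileOffset(tile_id=tid, dx=ex - ox, dy=ey - oy)
    return offsets, excluded


@dataclass
class GlobalIndex:
    """All retained records of a chip in the global nm frame."""

    barcodes: np.ndarray  # |S32
    x_nm: np.ndarray  # float64
    y_nm: np.ndarray
    tile_ids: np.ndarray  # int32, per record
    calibration: ScaleCalibration
    offsets: dict[int, TileOffset] = field(default_factory=dict)
    duplicate_barcodes: int = 0  # records sharing a barcode with another tile

    def __len__(self) -> int:
        return len(self.barcodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#barcode\tx_nm\ty_nm\ttile_id\n")
            for bc, x, y, t in zip(
                self.barcodes.astype(str), self.x_nm, self.y_nm, self.tile_ids
            ):
                fh.write(f"{bc}\t{x:.1f}\t{y:.1f}\t{t}\n")


def apply_offsets(
    indexes: Sequence[TileIndex],
    offsets: Mapping[int, TileOffset],
    calibration: ScaleCalibration,
) -> GlobalIndex:
    """Translate every tile's records and convert to nm.

    global = (local + offset) * nm_per_unit.  The record count is conserved;
    barcodes occurring in more than one tile are counted (they cannot be
    disambiguated downstream and are reported, not dropped here).
    """
    missing = [ix.tile_id for ix in indexes if ix.tile_id not in offsets]
    if missing:
        raise StitchError(f"no offset for tiles {missing}")
    parts_bc, parts_x, parts_y, parts_t = [], [], [], []
    for ix in indexes:
        off = offsets[ix.tile_id]
        parts_bc.append(ix.barcodes)
        parts_x.append((ix.x.astype(np.float64) + off.dx) * calibration.nm_per_unit)
        parts_y.append((ix.y.astype(np.float64) + off.dy) * calibration.nm_per_unit)
        parts_t.append(np.full(len(ix), ix.tile_id, dtype=np.int32))
    barcodes = np.concatenate(parts_bc) if parts_bc else np.empty(0, dtype="S32")
    gi = GlobalIndex(
        barcodes=barcodes,
        x_nm=np.concatenate(parts_x) if parts_x else np.empty(0),
        y_nm=np.concatenate(parts_y) if parts_y else np.empty(0),
        tile_ids=np.concatenate(parts_t) if parts_t else np.empty(0, dtype=np.int32),
        calibration=calibration,
        offsets=dict(offsets),
    )
    if len(barcodes):
        uniq, counts = np.unique(barcodes, return_counts=True)
        gi.duplicate_barcodes = int(counts[counts > 1].sum())
    return gi


# ---------------------------------------------------------------------------
# persistence: same record idea as the tile index, nm coordinates as f64,
# plus a header block carrying calibration and per-tile offsets.

_MAGIC = b"NVSG"
_VERSION = 1


def write_global_index(gi: GlobalIndex, path: str | Path) -> None:
    n = len(gi)
    offs = sorted(gi.offsets.values(), key=lambda o: o.tile_id)
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sBdIQ", _MAGIC, _VERSION, gi.calibration.nm_per_unit, len(offs), n))
        for o in offs:
            fh.write(struct.pack("<Idd", o.tile_id, o.dx, o.dy))
        rec = np.empty(n, dtype=[("bc", "<u8"), ("x", "<f8"), ("y", "<f8"), ("t", "<i4")])
        rec["bc"] = pack_barcodes(gi.barcodes)
        rec["x"] = gi.x_nm
        rec["y"] = gi.y_nm
        rec["t"] = gi.tile_ids
        fh.write(rec.tobytes())


def read_global_index(path: str | Path) -> GlobalIndex:
    blob = Path(path).read_bytes()
    head = struct.Struct("<4sBdIQ")
    if len(blob) < head.size:
        raise IndexFormatError(f"file too short for header: {path}")
    magic, version, nm_per_unit, n_off, n = head.unpack_from(blob)
    if magic != _MAGIC or version != _VERSION:
        raise IndexFormatError(f"bad magic/version in {path}")
    pos = head.size
    off_s = struct.Struct("<Idd")
    offsets = {}
    for _ in range(n_off):
        tid, dx, dy = off_s.unpack_from(blob, pos)
        offsets[tid] = TileOffset(tid, dx, dy)
        pos += off_s.size
    body = blob[pos:]
    if len(body) != n * 28:
        raise IndexFormatError(f"expected {n * 28} record bytes, found {len(body)} in {path}")
    rec = np.frombuffer(body, dtype=[("bc", "<u8"), ("x", "<f8"), ("y", "<f8"), ("t", "<i4")])
    gi = GlobalIndex(
        barcodes=unpack_barcodes(rec["bc"].copy()),
        x_nm=rec["x"].astype(np.float64),
        y_nm=rec["y"].astype(np.float64),
        tile_ids=rec["t"].astype(np.int32),
        calibration=ScaleCalibration(nm_per_unit=nm_per_unit),
        offsets=offsets,
    )
    if len(gi):
        uniq, counts = np.unique(gi.barcodes, return_counts=True)
        gi.duplicate_barcodes = int(counts[counts > 1].sum())
    return gi
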