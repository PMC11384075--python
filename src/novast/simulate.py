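"""Synthetic flow cell and spatial-library read generator.

Emulates the physical chip well enough to exercise the whole reconstruction
pipeline with known ground truth:

* a hexagonal nano-well lattice per tile, with each well independently
  receiving a unique pattern-conformant barcode with probability
  ``unique_occupancy`` (~80 % on real flow cells; the non-unique rest are
  simulated as empty wells),
* fiducial markers as barcode-free voids — a filled inner disk plus a thin
  outer ring per marker, matching the concentric-circle marks that anchor
  tiles to physical coordinates,
* staggered swaths: even-numbered swaths are shifted by one tile along the
  tile-row axis relative to odd-numbered ones,
* a spatial sequencing library whose molecules are sampled only from wells
  under a configurable tissue mask, with Poisson read duplication, per-base
  substitution errors and per-molecule 9-nt UMIs.

All randomness flows from ``SimConfig.seed``; a fixed seed yields
byte-identical FASTQ and truth outputs.

One raw coordinate unit corresponds to 25000/728 ~ 34.34 nm, so that a
728-unit spatial bin measures 25 um on the chip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hdmi_index import BarcodePattern, _IUPAC

__all__ = [
    "NM_PER_UNIT",
    "SimConfig",
    "TissueMask",
    "FlowcellTruth",
    "simulate_flowcell",
    "simulate_spatial_reads",
    "gene_catalog",
    "hex_lattice",
    "fiducial_centers_local",
    "tile_id_for",
]

#: Raw-unit to physical scale implied by the 728-unit ~ 25 um bin correspondence.
NM_PER_UNIT = 25000.0 / 728.0

_QUAL = "I"
_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Spatial-library read geometry: R1 carries the barcode, R2 the UMI + cDNA.
R1_LENGTH = 34
R2_LENGTH = 91
UMI_LENGTH = 9


class SimConfigError(ValueError):
    """Raised for physically impossible simulator configurations."""


@dataclass(frozen=True)
class TissueMask:
    """Union of axis-aligned rectangles in global raw units (x0, y0, x1, y1)."""

    rectangles: tuple[tuple[float, float, float, float], ...]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = np.zeros(x.shape, dtype=bool)
        for x0, y0, x1, y1 in self.rectangles:
            inside |= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        return inside

    @property
    def is_empty(self) -> bool:
        return not any(x1 > x0 and y1 > y0 for x0, y0, x1, y1 in self.rectangles)


def tile_id_for(surface: int, swath: int, row: int) -> int:
    """Tile naming convention: surface digit, swath digit, two-digit tile row."""
    return surface * 1000 + swath * 100 + row


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated chip.

    Geometry defaults model a scaled-down chip (6 x 6 tiles of 6000 x 6000
    raw units ~ 206 um) that keeps full-pipeline runs in the minutes range,
    with the ~80 % unique-well occupancy of real flow cells and fiducial
    circles within the radius ranges the detector expects (outer ~55, inner
    ~22 binned pixels at the default 25-unit bin).  The default well pitch
    of 15 raw units puts ~3 lattice sites per density-image pixel — enough
    that max-normalized occupancy separates cleanly from the fiducial voids
    at the standard 128 threshold, as it does on real cluster data.
    """

    n_swaths: int = 6
    tiles_per_swath: int = 6
    surface: int = 1
    tile_width: int = 6000
    tile_height: int = 6000
    well_pitch: float = 15.0
    unique_occupancy: float = 0.80
    fiducials_per_tile: int = 4
    fiducial_outer_radius: float = 1375.0  # 55 px at bin 25
    fiducial_inner_radius: float = 550.0  # 22 px at bin 25
    fiducial_ring_width: float = 125.0  # 5 px at bin 25
    barcode_pattern: BarcodePattern = field(default_factory=BarcodePattern)
    n_genes: int = 100
    gene_tag_length: int = 40
    tissue_mask: TissueMask | None = None
    n_molecules: int = 20_000
    reads_per_molecule: float = 3.0
    error_rate: float = 0.0
    tile_jitter_sd: float = 0.0
    tile_shifts: Mapping[int, tuple[float, float]] | None = None
    swath_offset_axis: str = "y"  # axis along which even swaths shift one tile
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.unique_occupancy <= 1:
            raise SimConfigError("unique_occupancy must lie in [0, 1]")
        if self.fiducial_inner_radius >= self.fiducial_outer_radius:
            raise SimConfigError("inner fiducial radius must be < outer radius")
        for name in ("n_swaths", "tiles_per_swath", "tile_width", "tile_height", "n_genes"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if self.swath_offset_axis not in ("x", "y"):
            raise SimConfigError("swath_offset_axis must be 'x' or 'y'")
        if self.tiles_per_swath > 99 or self.n_swaths > 6:
            raise SimConfigError("at most 6 swaths and 99 tile rows are supported")

    # -- derived geometry ---------------------------------------------------

    def tile_ids(self) -> list[int]:
        return [
            tile_id_for(self.surface, s, r)
            for s in range(1, self.n_swaths + 1)
            for r in range(1, self.tiles_per_swath + 1)
        ]

    def nominal_origin(self, swath: int, row: int) -> tuple[float, float]:
        """Global raw-unit origin of a tile; even swaths sit one tile lower."""
        ox = (swath - 1) * self.tile_width
        oy = (row - 1) * self.tile_height
        if swath % 2 == 0:
            if self.swath_offset_axis == "y":
                oy += self.tile_height
            else:
                ox += self.tile_width
        return float(ox), float(oy)

    def chip_extent(self) -> tuple[float, float]:
        w = self.n_swaths * self.tile_width
        h = (self.tiles_per_swath + 1) * self.tile_height
        if self.swath_offset_axis == "x":
            w, h = (self.n_swaths + 1) * self.tile_width, self.tiles_per_swath * self.tile_height
        return float(w), float(h)

    def default_tissue_mask(self) -> TissueMask:
        """Central rectangle covering roughly the middle quarter of the chip."""
        w, h = self.chip_extent()
        return TissueMask(((0.25 * w, 0.25 * h, 0.75 * w, 0.75 * h),))

    def mask_from_tiles(self, tile_ids: Sequence[int]) -> TissueMask:
        """Tissue mask exactly covering the nominal footprint of given tiles."""
        rects = []
        for tid in tile_ids:
            swath, row = (tid // 100) % 10, tid % 100
            ox, oy = self.nominal_origin(swath, row)
            rects.append((ox, oy, ox + self.tile_width, oy + self.tile_height))
        return TissueMask(tuple(rects))


def lattice_in_frame(
    ox: float, oy: float, width: float, height: float, pitch: float
) -> tuple[np.ndarray, np.ndarray]:
    """Global hexagonal lattice points falling inside a rectangular frame.

    The lattice is anchored at the global origin: row ``i`` sits at
    ``y = i * pitch * sqrt(3)/2``, odd rows offset by ``pitch/2`` in x.
    Returns float global coordinates.
    """
    row_step = pitch * np.sqrt(3.0) / 2.0
    i0 = int(np.ceil(oy / row_step - 1e-9))
    i1 = int(np.floor((oy + height) / row_step + 1e-9))
    xs, ys = [], []
    for i in range(i0, i1 + 1):
        gy = i * row_step
        if gy < oy or gy >= oy + height:
            continue
        off = pitch / 2.0 if i % 2 else 0.0
        j0 = int(np.ceil((ox - off) / pitch - 1e-9))
        j1 = int(np.floor((ox + width - off) / pitch + 1e-9))
        gx = off + pitch * np.arange(j0, j1 + 1, dtype=np.float64)
        gx = gx[(gx >= ox) & (gx < ox + width)]
        xs.append(gx)
        ys.append(np.full(len(gx), gy))
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


def hex_lattice(width: int, height: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer coordinates of hexagonal lattice sites inside [0,width) x [0,height)."""
    gx, gy = lattice_in_frame(0.0, 0.0, float(width), float(height), pitch)
    return np.round(gx).astype(np.int64), np.round(gy).astype(np.int64)


def fiducial_centers_local(config: SimConfig) -> np.ndarray:
    """(k, 2) local-unit fiducial centers; constant placement across tiles."""
    k = config.fiducials_per_tile
    if k == 0:
        return np.empty((0, 2), dtype=float)
    w, h = config.tile_width, config.tile_height
    if k == 1:
        centers = [(w / 2, h / 2)]
    elif k == 2:
        centers = [(w / 4, h / 2), (3 * w / 4, h / 2)]
    elif k == 4:
        centers = [(w / 4, h / 4), (3 * w / 4, h / 4), (w / 4, 3 * h / 4), (3 * w / 4, 3 * h / 4)]
    else:
        raise SimConfigError("fiducials_per_tile must be 0, 1, 2 or 4")
    centers = np.asarray(centers, dtype=float)
    reach = config.fiducial_outer_radius + config.fiducial_ring_width
    if (
        (centers[:, 0] - reach < 0).any()
        or (centers[:, 1] - reach < 0).any()
        or (centers[:, 0] + reach > w).any()
        or (centers[:, 1] + reach > h).any()
    ):
        raise SimConfigError("fiducial markers do not fit inside the tile")
    return centers


@dataclass
class FlowcellTruth:
    """Ground truth of one simulated chip: every well's barcode and position."""

    config: SimConfig
    tile_ids: list[int]
    well_x: dict[int, np.ndarray]  # local raw units, int
    well_y: dict[int, np.ndarray]
    well_barcodes: dict[int, np.ndarray]  # |S32
    tile_origins: dict[int, tuple[float, float]]  # true (possibly jittered)
    nominal_origins: dict[int, tuple[float, float]]
    fiducial_centers: dict[int, np.ndarray]  # local units, (k, 2)
    nm_per_unit: float = NM_PER_UNIT

    @property
    def n_wells(self) -> int:
        return sum(len(v) for v in self.well_x.values())

    def global_positions(self, tile_id: int) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.tile_origins[tile_id]
        return self.well_x[tile_id] + ox, self.well_y[tile_id] + oy

    def barcode_positions(self) -> pd.DataFrame:
        """All wells as a DataFrame (barcode, tile_id, local/global coordinates)."""
        frames = []
        for tid in self.tile_ids:
            gx, gy = self.global_positions(tid)
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": self.well_barcodes[tid].astype(str),
                        "tile_id": tid,
                        "local_x": self.well_x[tid],
                        "local_y": self.well_y[tid],
                        "global_x_nm": gx * self.nm_per_unit,
                        "global_y_nm": gy * self.nm_per_unit,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write(self, out_dir: str | Path) -> None:
        """Write tab-separated truth sidecars with commented headers."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tiles = pd.DataFrame(
            {
                "tile_id": self.tile_ids,
                "origin_x": [self.tile_origins[t][0] for t in self.tile_ids],
                "origin_y": [self.tile_origins[t][1] for t in self.tile_ids],
                "nominal_x": [self.nominal_origins[t][0] for t in self.tile_ids],
                "nominal_y": [self.nominal_origins[t][1] for t in self.tile_ids],
            }
        )
        _write_commented_tsv(tiles, out_dir / "truth_tiles.tsv")
        _write_commented_tsv(self.barcode_positions(), out_dir / "truth_wells.tsv")


def _write_commented_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# barcode sampling


def _degenerate_space(pattern: BarcodePattern) -> tuple[np.ndarray, np.ndarray, list[str]]:
    positions = pattern.degenerate_positions()
    alphabets = [_IUPAC[pattern.template[i]] for i in positions]
    radix = np.array([len(a) for a in alphabets], dtype=np.uint64)
    return positions, radix, alphabets


def _sample_unique_barcodes(n: int, pattern: BarcodePattern, rng: np.random.Generator) -> np.ndarray:
    """Draw n distinct pattern-conformant barcodes as an |S32 array."""
    positions, radix, alphabets = _degenerate_space(pattern)
    k = len(positions)
    space = float(np.prod(radix.astype(float)))
    if n > 0.5 * space:
        raise SimConfigError(f"cannot draw {n} unique barcodes from a space of {space:.3g}")
    mult = np.ones(k, dtype=np.uint64)
    for i in range(1, k):
        mult[i] = mult[i - 1] * radix[i - 1]

    idx = rng.integers(0, radix[None, :], size=(n, k), dtype=np.uint64)
    keys = (idx * mult[None, :]).sum(axis=1, dtype=np.uint64)
    while True:
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        dup_sorted = np.zeros(n, dtype=bool)
        dup_sorted[1:] = sorted_keys[1:] == sorted_keys[:-1]
        dup = np.zeros(n, dtype=bool)
        dup[order] = dup_sorted
        if not dup.any():
            break
        m = int(dup.sum())
        idx[dup] = rng.integers(0, radix[None, :], size=(m, k), dtype=np.uint64)
        keys[dup] = (idx[dup] * mult[None, :]).sum(axis=1, dtype=np.uint64)

    out = np.empty((n, 32), dtype=np.uint8)
    for j, sym in enumerate(pattern.template):
        if j not in positions:
            out[:, j] = ord(sym)
    for col, (j, alpha) in enumerate(zip(positions, alphabets)):
        letters = np.frombuffer(alpha.encode(), dtype=np.uint8)
        out[:, j] = letters[idx[:, col].astype(np.intp)]
    return out.view("S32").ravel()


# ---------------------------------------------------------------------------
# flow-cell simulation


def simulate_flowcell(config: SimConfig, out_dir: str | Path | None = None) -> FlowcellTruth:
    """Simulate the barcode-bearing chip; optionally write per-tile FASTQ.

    Each lattice site is occupied (receives a unique barcode) with
    probability ``unique_occupancy``; sites under a fiducial marker are
    always empty.  With ``out_dir`` given, one 4-line-record FASTQ per tile
    is written under ``<out_dir>/hdmi/`` with read names
    ``@SIM:1:FC1:1:<tile>:<x>:<y>``.
    """
    rng = np.random.default_rng(config.seed)
    base_centers = fiducial_centers_local(config)

    tile_ids = config.tile_ids()
    shifts = dict(config.tile_shifts or {})
    well_x: dict[int, np.ndarray] = {}
    well_y: dict[int, np.ndarray] = {}
    origins: dict[int, tuple[float, float]] = {}
    nominal: dict[int, tuple[float, float]] = {}
    fid: dict[int, np.ndarray] = {}

    w, h = float(config.tile_width), float(config.tile_height)
    for tid in tile_ids:
        swath, row = (tid // 100) % 10, tid % 100
        ox, oy = config.nominal_origin(swath, row)
        nominal[tid] = (ox, oy)
        # Wells and fiducial marks live on an ideal global lattice; what
        # varies per tile is where the sequencer's imaging frame sits.  An
        # apparent content shift of +s in the read coordinates corresponds
        # to a frame displaced by -s.
        fx = fy = 0.0
        if config.tile_jitter_sd > 0:
            fx, fy = rng.normal(0.0, config.tile_jitter_sd, size=2)
        sx, sy = shifts.get(tid, (0.0, 0.0))
        fox, foy = ox + fx - sx, oy + fy - sy
        origins[tid] = (fox, foy)

        gx, gy = lattice_in_frame(fox, foy, w, h, config.well_pitch)
        # fiducial marks of this tile, at their ideal global positions
        centers_global = base_centers + np.array([ox, oy])
        void = np.zeros(len(gx), dtype=bool)
        for cx, cy in centers_global:
            d = np.hypot(gx - cx, gy - cy)
            # +1 unit guard: local coordinates are rounded to integers, which
            # must not move an edge well back inside the void
            void |= d <= config.fiducial_inner_radius + 1.0
            void |= np.abs(d - config.fiducial_outer_radius) <= config.fiducial_ring_width / 2.0 + 1.0
        keep = (rng.random(len(gx)) < config.unique_occupancy) & ~void
        lx = np.round(gx[keep] - fox).astype(np.int64)
        ly = np.round(gy[keep] - foy).astype(np.int64)
        ok = (lx >= 0) & (lx < config.tile_width) & (ly >= 0) & (ly < config.tile_height)
        lx, ly = lx[ok], ly[ok]
        # emit records in spatially mixed order, as clusters come off the
        # instrument — downstream identification subsets rely on the first
        # reads of a tile sampling the whole tile area
        perm = rng.permutation(len(lx))
        well_x[tid] = lx[perm]
        well_y[tid] = ly[perm]
        fid[tid] = centers_global - np.array([fox, foy])

    total = sum(len(well_x[t]) for t in tile_ids)
    barcodes = _sample_unique_barcodes(total, config.barcode_pattern, rng)
    well_barcodes: dict[int, np.ndarray] = {}
    pos = 0
    for tid in tile_ids:
        n = len(well_x[tid])
        well_barcodes[tid] = barcodes[pos : pos + n]
        pos += n

    truth = FlowcellTruth(
        config=config,
        tile_ids=tile_ids,
        well_x=well_x,
        well_y=well_y,
        well_barcodes=well_barcodes,
        tile_origins=origins,
        nominal_origins=nominal,
        fiducial_centers=fid,
    )

    if out_dir is not None:
        fastq_dir = Path(out_dir) / "hdmi"
        fastq_dir.mkdir(parents=True, exist_ok=True)
        qual = _QUAL * 32
        for tid in tile_ids:
            xs = well_x[tid].tolist()
            ys = well_y[tid].tolist()
            bcs = well_barcodes[tid].astype(str).tolist()
            with open(fastq_dir / f"tile_{tid}.fastq", "w") as fh:
                fh.write(
                    "".join(
                        f"@SIM:1:FC1:1:{tid}:{x}:{y} 1:N:0:1\n{bc}\n+\n{qual}\n"
                        for x, y, bc in zip(xs, ys, bcs)
                    )
                )
    return truth


# ---------------------------------------------------------------------------
# spatial-library simulation


def gene_catalog(config: SimConfig) -> pd.DataFrame:
    """Synthetic transcriptome: one unique random tag per gene.

    Deterministic given the config seed; shared by the simulator (read
    payloads) and the quantifier (gene lookup).
    """
    rng = np.random.default_rng([config.seed, 2])
    n, L = config.n_genes, config.gene_tag_length
    while True:
        mat = _LETTERS[rng.integers(0, 4, size=(n, L), dtype=np.int64)]
        tags = mat.view(f"S{L}").ravel().astype(str)
        if len(set(tags)) == n:
            break
    return pd.DataFrame({"gene_id": [f"gene_{i:04d}" for i in range(n)], "tag": tags})


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitutions: each base flips to a different base with prob rate."""
    if rate <= 0:
        return mat
    codes = np.zeros_like(mat)
    for i, b in enumerate(b"ACGT"):
        codes[mat == b] = i
    hit = rng.random(mat.shape) < rate
    offset = rng.integers(1, 4, size=mat.shape, dtype=np.int64)
    codes = np.where(hit, (codes + offset) % 4, codes)
    return _LETTERS[codes]


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    L = mat.shape[1]
    return mat.view(f"S{L}").ravel().astype(str).tolist()


def simulate_spatial_reads(
    config: SimConfig,
    truth: FlowcellTruth,
    out_dir: str | Path,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate the paired spatial library (R1 34 nt / R2 91 nt) with ground truth.

    Molecules are sampled uniformly from occupied wells inside the tissue
    mask; each molecule receives a gene, a 9-nt UMI and ``1 + Poisson``
    duplicate reads sharing barcode and UMI.  R1 is the well barcode padded
    to 34 nt; R2 is UMI + gene tag + random filler to 91 nt.  Substitution
    errors are applied independently per base at ``error_rate``.

    Returns the per-read truth table and writes ``spatial_R1.fastq``,
    ``spatial_R2.fastq``, ``genes.tsv`` and ``truth_reads.tsv`` to out_dir.
    """
    rng = np.random.default_rng([config.seed, 1])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if genes is None:
        genes = gene_catalog(config)
    _write_commented_tsv(genes, out_dir / "genes.tsv")

    mask = config.tissue_mask or config.default_tissue_mask()
    cand = []
    for tid in truth.tile_ids:
        gx, gy = truth.global_positions(tid)
        inside = mask.contains(gx, gy)
        if inside.any():
            cand.append(
                (
                    np.full(int(inside.sum()), tid),
                    truth.well_x[tid][inside],
                    truth.well_y[tid][inside],
                    gx[inside],
                    gy[inside],
                    truth.well_barcodes[tid][inside],
                )
            )
    empty_cols = [
        "read_id", "molecule_id", "tile_id", "local_x", "local_y",
        "global_x_nm", "global_y_nm", "barcode", "gene_id", "umi",
    ]
    r1_path, r2_path = out_dir / "spatial_R1.fastq", out_dir / "spatial_R2.fastq"
    if not cand:
        warnings.warn("tissue mask covers no occupied wells; empty spatial library", stacklevel=2)
        r1_path.write_text("")
        r2_path.write_text("")
        reads = pd.DataFrame(columns=empty_cols)
        _write_commented_tsv(reads, out_dir / "truth_reads.tsv")
        return reads

    tile_c = np.concatenate([c[0] for c in cand])
    lx_c = np.concatenate([c[1] for c in cand])
    ly_c = np.concatenate([c[2] for c in cand])
    gx_c = np.concatenate([c[3] for c in cand])
    gy_c = np.concatenate([c[4] for c in cand])
    bc_c = np.concatenate([c[5] for c in cand])

    n_mol = config.n_molecules
    pick = rng.integers(0, len(bc_c), size=n_mol)
    gene_idx = rng.integers(0, config.n_genes, size=n_mol)
    umi_mat = _LETTERS[rng.integers(0, 4, size=(n_mol, UMI_LENGTH), dtype=np.int64)]
    extra = max(config.reads_per_molecule - 1.0, 0.0)
    dup = 1 + rng.poisson(extra, size=n_mol)

    mol_of_read = np.repeat(np.arange(n_mol), dup)
    n_reads = len(mol_of_read)
    dup_idx = np.arange(n_reads) - np.repeat(np.cumsum(dup) - dup, dup)

    bc_mat = bc_c[pick].view(np.uint8).reshape(n_mol, 32)
    tags = genes["tag"].to_numpy().astype(f"S{config.gene_tag_length}")
    tag_mat = tags[gene_idx].view(np.uint8).reshape(n_mol, config.gene_tag_length)

    r1 = np.empty((n_reads, R1_LENGTH), dtype=np.uint8)
    r1[:, :32] = bc_mat[mol_of_read]
    r1[:, 32:] = _LETTERS[rng.integers(0, 4, size=(n_reads, R1_LENGTH - 32), dtype=np.int64)]

    r2 = np.empty((n_reads, R2_LENGTH), dtype=np.uint8)
    r2[:, :UMI_LENGTH] = umi_mat[mol_of_read]
    r2[:, UMI_LENGTH : UMI_LENGTH + config.gene_tag_length] = tag_mat[mol_of_read]
    filler = R2_LENGTH - UMI_LENGTH - config.gene_tag_length
    r2[:, UMI_LENGTH + config.gene_tag_length :] = _LETTERS[
        rng.integers(0, 4, size=(n_reads, filler), dtype=np.int64)
    ]

    r1 = _apply_errors(r1, config.error_rate, rng)
    r2 = _apply_errors(r2, config.error_rate, rng)

    perm = rng.permutation(n_reads)
    mol_of_read, dup_idx, r1, r2 = mol_of_read[perm], dup_idx[perm], r1[perm], r2[perm]

    names = [f"SPAT:{m}:{d}" for m, d in zip(mol_of_read.tolist(), dup_idx.tolist())]
    q1, q2 = _QUAL * R1_LENGTH, _QUAL * R2_LENGTH
    with open(r1_path, "w") as fh:
        fh.write("".join(f"@{nm} 1:N:0:1\n{s}\n+\n{q1}\n" for nm, s in zip(names, _rows_to_strings(r1))))
    with open(r2_path, "w") as fh:
        fh.write("".join(f"@{nm} 2:N:0:1\n{s}\n+\n{q2}\n" for nm, s in zip(names, _rows_to_strings(r2))))

    gene_ids = genes["gene_id"].to_numpy()
    reads = pd.DataFrame(
        {
            "read_id": names,
            "molecule_id": mol_of_read,
            "tile_id": tile_c[pick][mol_of_read],
            "local_x": lx_c[pick][mol_of_read],
            "local_y": ly_c[pick][mol_of_read],
            "global_x_nm": gx_c[pick][mol_of_read] * truth.nm_per_unit,
            "global_y_nm": gy_c[pick][mol_of_read] * truth.nm_per_unit,
            "barcode": bc_c[pick][mol_of_read].astype(str),
            "gene_id": gene_ids[gene_idx[mol_of_read]],
            "umi": _rows_to_strings(umi_mat[mol_of_read]),
        }
    )
    _write_commented_tsv(reads, out_dir / "truth_reads.tsv")
    return reads
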