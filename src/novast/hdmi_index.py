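"""Per-tile spatial-barcode indexing.

The first sequencing pass reads one 32-mer spatial barcode per occupied
nano-well; the sequencer's read names carry the tile number and the local
(x, y) coordinate of the well within that tile.  This module parses the
demultiplexed per-tile FASTQ, validates each barcode against the expected
degenerate design (12 constant bases followed by 20 degenerate bases by
default), and persists compact binary per-tile indexes plus a small subset
of reads kept aside for later tissue-tile identification.
"""

from __future__ import annotations

import gzip
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BarcodePattern",
    "DEFAULT_TEMPLATE",
    "ValidationResult",
    "TileRecord",
    "TileIndex",
    "IndexFormatError",
    "ReadNameError",
    "parse_read_name",
    "decompose_tile_id",
    "validate_barcode",
    "build_tile_index",
    "write_index",
    "read_index",
    "pack_barcodes",
    "unpack_barcodes",
    "iter_fastq",
]

#: Constant sequencing-primer block followed by the degenerate barcode block.
DEFAULT_TEMPLATE = "CTCTTCCGATCT" + "NNVNNVNNVNNVNNVNNNNN"

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "N": "ACGT",
    "V": "ACG",  # not T
    "B": "CGT",  # not A
}

_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T -> 2-bit codes


class IndexFormatError(ValueError):
    """Raised when a binary index file is malformed or truncated."""


class ReadNameError(ValueError):
    """Raised when a read name does not follow the sequencer convention."""


@dataclass(frozen=True)
class BarcodePattern:
    """Expected barcode design as a 32-symbol IUPAC template.

    ``N`` admits any base, ``V`` excludes T, ``B`` excludes A; other symbols
    are constant positions that must match exactly.
    """

    template: str = DEFAULT_TEMPLATE
    max_constant_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.template) != 32:
            raise ValueError(f"template must be 32 symbols, got {len(self.template)}")
        bad = set(self.template) - set(_IUPAC)
        if bad:
            raise ValueError(f"unsupported template symbols: {sorted(bad)}")
        if self.max_constant_mismatches != 0:
            raise NotImplementedError("only exact constant-block matching is supported")

    @property
    def length(self) -> int:
        return len(self.template)

    def allowed(self, position: int) -> str:
        """Bases admitted at a template position."""
        return _IUPAC[self.template[position]]

    def allowed_table(self) -> np.ndarray:
        """(256, L) boolean lookup: table[byte, pos] == base allowed at pos."""
        table = np.zeros((256, self.length), dtype=bool)
        for pos, sym in enumerate(self.template):
            for base in _IUPAC[sym]:
                table[ord(base), pos] = True
        return table

    def degenerate_positions(self) -> np.ndarray:
        """Indices of the degenerate (N/V/B) template positions."""
        return np.array(
            [i for i, s in enumerate(self.template) if s in "NVB"], dtype=np.int64
        )


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reason: str | None = None
    position: int | None = None

    def __bool__(self) -> bool:
        return self.valid


def validate_barcode(seq: str, pattern: BarcodePattern) -> ValidationResult:
    """Check one barcode against the degenerate template, position by position."""
    if len(seq) != pattern.length:
        return ValidationResult(False, "length", None)
    for i, base in enumerate(seq):
        if base not in pattern.allowed(i):
            return ValidationResult(False, f"symbol {base!r} not in {pattern.allowed(i)}", i)
    return ValidationResult(True)


def parse_read_name(name: str) -> tuple[int, int, int, int]:
    """Extract (lane, tile, x, y) from a sequencer read name.

    Names follow ``instrument:run:flowcell:lane:tile:x:y`` with optional
    whitespace-separated trailing metadata and an optional leading ``@``.
    """
    head = name.split(maxsplit=1)[0].lstrip("@") if name.strip() else ""
    fields = head.split(":")
    if len(fields) < 7:
        raise ReadNameError(f"read name has {len(fields)} colon fields, need >=7: {name!r}")
    try:
        lane, tile, x, y = (int(f) for f in fields[3:7])
    except ValueError as exc:
        raise ReadNameError(f"non-integer lane/tile/x/y in read name {name!r}") from exc
    return lane, tile, x, y


def decompose_tile_id(tile_id: int) -> tuple[int, int, int]:
    """Split a 4-digit tile id into (surface, swath, tile row)."""
    if not 1000 <= tile_id <= 9999:
        raise ValueError(f"tile id must be 4 digits, got {tile_id}")
    return tile_id // 1000, (tile_id // 100) % 10, tile_id % 100


@dataclass(frozen=True)
class TileRecord:
    barcode: str
    x: int
    y: int


@dataclass
class TileIndex:
    """Valid barcodes of one tile with their local raw-unit coordinates.

    ``subset_size`` records are reserved (the first ones seen, deterministic)
    for the later step that identifies which tiles lie under a tissue section.
    """

    tile_id: int
    barcodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype="S32")
    )  # |S32 bytes
    x: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint32))
    y: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint32))
    subset_size: int = 10_000

    def __post_init__(self) -> None:
        if not (len(self.barcodes) == len(self.x) == len(self.y)):
            raise ValueError("barcodes, x and y must have equal length")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def subset(self) -> "TileIndex":
        """The reserved identification subset (first min(subset_size, n) records)."""
        k = min(self.subset_size, len(self))
        return TileIndex(self.tile_id, self.barcodes[:k], self.x[:k], self.y[:k], k)

    def records(self) -> Iterator[TileRecord]:
        for bc, xx, yy in zip(self.barcodes, self.x, self.y):
            yield TileRecord(bc.decode(), int(xx), int(yy))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TileIndex):
            return NotImplemented
        return (
            self.tile_id == other.tile_id
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )


# ---------------------------------------------------------------------------
# FASTQ parsing


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a 4-line FASTQ file (optionally gzipped)."""
    with _open_text(Path(path)) as fh:
        while True:
            name = fh.readline()
            if not name:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise IndexFormatError(f"truncated FASTQ record in {path}")
            if not name.startswith("@") or not plus.startswith("+"):
                raise IndexFormatError(f"malformed FASTQ record in {path}")
            yield name.rstrip("\n"), seq


def _read_fastq_arrays(path: Path) -> tuple[list[str], list[str]]:
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise IndexFormatError(f"FASTQ line count not a multiple of 4 in {path}")
    return lines[0::4], lines[1::4]


def build_tile_index(
    fastq_path: str | Path,
    pattern: BarcodePattern | None = None,
    tile_id: int | None = None,
    subset_size: int = 10_000,
) -> tuple[TileIndex, dict]:
    """Parse one tile's FASTQ into a :class:`TileIndex` of valid barcodes.

    Returns the index and a stats dict with ``total``, ``valid`` and
    ``invalid`` counts (valid + invalid == total always).
    """
    pattern = pattern or BarcodePattern()
    names, seqs = _read_fastq_arrays(Path(fastq_path))
    n = len(names)
    if n == 0:
        warnings.warn(f"empty FASTQ file: {fastq_path}", stacklevel=2)
        return (
            TileIndex(tile_id if tile_id is not None else 0, subset_size=subset_size),
            {"total": 0, "valid": 0, "invalid": 0},
        )

    lane0, tile0, _, _ = parse_read_name(names[0])
    if tile_id is None:
        tile_id = tile0

    xs = np.empty(n, dtype=np.uint32)
    ys = np.empty(n, dtype=np.uint32)
    for i, nm in enumerate(names):
        head = nm.split(" ", 1)[0]
        parts = head.split(":")
        if len(parts) < 7:
            raise ReadNameError(f"read name has {len(parts)} colon fields, need >=7: {nm!r}")
        xs[i] = int(parts[5])
        ys[i] = int(parts[6])

    # vectorized template validation over a byte matrix
    length = pattern.length
    lens = np.fromiter((len(s) for s in seqs), count=n, dtype=np.int64)
    ok_len = lens == length
    valid = np.zeros(n, dtype=bool)
    if ok_len.any():
        idx = np.flatnonzero(ok_len)
        mat = np.frombuffer(
            "".join(seqs[i] for i in idx).encode("ascii"), dtype=np.uint8
        ).reshape(len(idx), length)
        table = pattern.allowed_table()
        valid[idx] = table[mat, np.arange(length)].all(axis=1)

    keep = np.flatnonzero(valid)
    barcodes = np.array([seqs[i] for i in keep], dtype="S32")
    index = TileIndex(tile_id, barcodes, xs[keep], ys[keep], subset_size)
    stats = {
        "total": n,
        "valid": int(valid.sum()),
        "invalid": int(n - valid.sum()),
        "lane": lane0,
    }
    return index, stats


# ---------------------------------------------------------------------------
# Binary persistence: magic "NVST", version u8, tile_id u32, n u64,
# then n fixed 16-byte records (u64 2-bit-packed barcode, u32 x, u32 y),
# all little-endian.

_MAGIC = b"NVST"
_VERSION = 1
_HEADER = struct.Struct("<4sBIQ")


def pack_barcodes(barcodes: np.ndarray) -> np.ndarray:
    """2-bit-pack |S32 ACGT barcodes into uint64 (base i in bits 2i..2i+1)."""
    if len(barcodes) == 0:
        return np.empty(0, dtype=np.uint64)
    mat = barcodes.view(np.uint8).reshape(len(barcodes), 32)
    codes = np.zeros_like(mat)
    for byte, code in _BASE_CODE.items():
        codes[mat == byte] = code
    shifts = (2 * np.arange(32, dtype=np.uint64))[None, :]
    return (codes.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)


def unpack_barcodes(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_barcodes`."""
    if len(packed) == 0:
        return np.empty(0, dtype="S32")
    shifts = (2 * np.arange(32, dtype=np.uint64))[None, :]
    codes = (packed[:, None] >> shifts) & np.uint64(3)
    letters = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
    return letters[codes.astype(np.intp)].view("S32").ravel()


def write_index(index: TileIndex, path: str | Path) -> None:
    """Write a tile index in the fixed binary layout (lossless round trip)."""
    path = Path(path)
    n = len(index)
    rec = np.empty(n, dtype=[("bc", "<u8"), ("x", "<u4"), ("y", "<u4")])
    rec["bc"] = pack_barcodes(index.barcodes)
    rec["x"] = index.x
    rec["y"] = index.y
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, index.tile_id, n))
        fh.write(rec.tobytes())


def read_index(path: str | Path, subset_size: int = 10_000) -> TileIndex:
    """Read a binary tile index; raises :class:`IndexFormatError` on corruption."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER.size:
        raise IndexFormatError(f"file too short for header: {path}")
    magic, version, tile_id, n = _HEADER.unpack_from(blob)
    if magic != _MAGIC:
        raise IndexFormatError(f"bad magic {magic!r} in {path}")
    if version != _VERSION:
        raise IndexFormatError(f"unsupported index version {version} in {path}")
    body = blob[_HEADER.size :]
    if len(body) != n * 16:
        raise IndexFormatError(
            f"expected {n * 16} record bytes, found {len(body)} in {path}"
        )
    rec = np.frombuffer(body, dtype=[("bc", "<u8"), ("x", "<u4"), ("y", "<u4")])
    return TileIndex(
        tile_id,
        unpack_barcodes(rec["bc"].copy()),
        rec["x"].astype(np.uint32),
        rec["y"].astype(np.uint32),
        subset_size,
    )


def write_indexes(
    indexes: Sequence[TileIndex], out_dir: str | Path, write_subsets: bool = True
) -> list[Path]:
    """Write one ``tile_<id>.nvst`` (and ``tile_<id>.subset.nvst``) per tile."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx in indexes:
        p = out_dir / f"tile_{idx.tile_id}.nvst"
        write_index(idx, p)
        paths.append(p)
        if write_subsets:
            write_index(idx.subset, out_dir / f"tile_{idx.tile_id}.subset.nvst")
    return paths
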