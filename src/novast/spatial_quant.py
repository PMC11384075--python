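"""Spatial-library quantification.

The spatial sequencing library pairs a barcode read (R1: the 34-nt well
barcode, of which the first 31 nt are used for matching) with a cDNA read
(R2: 9-nt UMI followed by transcript sequence).  Processing steps:

1. identify the tiles lying under the tissue by matching barcodes from the
   first million reads against each tile's reserved identification subset;
2. build a whitelist of 31-nt-trimmed barcodes from those tiles;
3. match each read's barcode against the whitelist exactly or at Hamming
   distance 1 (unique hits only — ambiguous hits are discarded);
4. assign the gene (internal path: exact transcript-tag lookup; external
   path: import a barcode x gene sparse matrix produced by an aligner);
5. collapse UMIs within Hamming distance 1 into molecules (connected
   components, the ``1MM_All`` reading);
6. write GEM: tab-separated (geneID, x, y, MIDCount) rows on the native
   coordinate grid, the interchange format of the Stereo-seq ecosystem.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .hdmi_index import TileIndex, iter_fastq
from .stitch import GlobalIndex, ScaleCalibration

__all__ = [
    "Whitelist",
    "QuantError",
    "identify_tiles",
    "build_whitelist",
    "match_barcode",
    "dedup_umis",
    "quantify",
    "import_counts",
    "export_counts",
    "write_gem",
    "read_gem",
    "load_gene_lookup",
]

CB_LENGTH = 31
UMI_EXTRACTED = 9  # bases taken from the start of R2
UMI_USED = 8  # bases actually used for deduplication


class QuantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tissue-tile identification


def identify_tiles(
    r1_fastq: str | Path,
    subsets: Mapping[int, TileIndex],
    n_reads: int = 1_000_000,
    min_hits: int = 10,
) -> tuple[list[int], dict[int, int]]:
    """Select the tiles covered by tissue from the first reads of the library.

    A tile is selected when at least ``min_hits`` distinct barcodes of its
    reserved identification subset occur (exact 31-nt match) among the
    first ``n_reads`` barcode reads.  Random 31-mers essentially never
    collide with a subset (~n_reads * |subset| / 4^31), so chance selection
    is negligible.
    """
    lookup: dict[str, int] = {}
    for tid, sub in subsets.items():
        for bc in sub.barcodes.astype(str):
            lookup[bc[:CB_LENGTH]] = tid

    seen: dict[int, set] = defaultdict(set)
    total = 0
    for _, seq in iter_fastq(r1_fastq):
        if total >= n_reads:
            break
        total += 1
        cb = seq[:CB_LENGTH]
        tid = lookup.get(cb)
        if tid is not None:
            seen[tid].add(cb)

    if total == 0:
        raise QuantError(f"no reads in {r1_fastq}")
    hits = {tid: len(s) for tid, s in seen.items()}
    selected = sorted(tid for tid, k in hits.items() if k >= min_hits)
    if not selected:
        raise QuantError(
            f"no tile reached {min_hits} distinct subset hits in {total} reads; "
            f"best: {sorted(hits.items(), key=lambda kv: -kv[1])[:5]}"
        )
    return selected, dict(hits)


# ---------------------------------------------------------------------------
# whitelist


@dataclass
class Whitelist:
    """31-nt-trimmed barcodes of the tissue-covered tiles with positions.

    Barcodes whose 31-nt prefixes collide after trimming are dropped
    entirely (both sides) and counted in ``collisions``.
    """

    entries: dict[str, tuple[float, float]]  # bc31 -> (x_nm, y_nm)
    provenance: tuple[int, ...] = ()
    collisions: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cb: str) -> bool:
        return cb in self.entries

    def position(self, cb: str) -> tuple[float, float]:
        return self.entries[cb]


def build_whitelist(gi: GlobalIndex, selected_tiles: Sequence[int]) -> Whitelist:
    """Extract the whitelist from the stitched index of the selected tiles."""
    if not selected_tiles:
        raise QuantError("no tiles selected")
    sel = np.isin(gi.tile_ids, np.asarray(selected_tiles))
    if not sel.any():
        raise QuantError(f"selected tiles {list(selected_tiles)} have no records")
    trimmed = gi.barcodes[sel].astype(str)
    trimmed = np.array([b[:CB_LENGTH] for b in trimmed])
    xs, ys = gi.x_nm[sel], gi.y_nm[sel]

    uniq, first_idx, counts = np.unique(trimmed, return_index=True, return_counts=True)
    dup = counts > 1
    collisions = int(counts[dup].sum())
    entries = {
        bc: (float(xs[i]), float(ys[i]))
        for bc, i, d in zip(uniq, first_idx, dup)
        if not d
    }
    if not entries:
        raise QuantError("whitelist is empty after trim-collision removal")
    return Whitelist(entries=entries, provenance=tuple(sorted(set(selected_tiles))), collisions=collisions)


# ---------------------------------------------------------------------------
# barcode matching and UMI deduplication

_BASES = "ACGT"


def match_barcode(cb: str, wl: Whitelist) -> str | None:
    """Whitelist assignment with at most one mismatch.

    Exact match wins; otherwise, if exactly one whitelist entry lies at
    Hamming distance 1, that entry is returned; none or several candidates
    give ``None`` (the read stays unassigned).  A non-ACGT base in ``cb``
    cannot match exactly, but substituting it still counts as the single
    allowed mismatch.
    """
    if cb in wl.entries:
        return cb
    hits: set[str] = set()
    for i, orig in enumerate(cb):
        prefix, suffix = cb[:i], cb[i + 1 :]
        for b in _BASES:
            if b == orig:
                continue
            cand = prefix + b + suffix
            if cand in wl.entries:
                hits.add(cand)
                if len(hits) > 1:
                    return None
    return hits.pop() if len(hits) == 1 else None


def _hamming1(a: str, b: str) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > 1:
                return False
    return d == 1


def dedup_umis(umis: Iterable[str]) -> int:
    """Number of molecules among UMIs of one (barcode, gene) group.

    UMIs within Hamming distance 1 are considered sequencing variants of
    the same molecule; the count is the number of connected components of
    the Hamming-1 graph over the distinct UMIs.
    """
    uniq = sorted(set(umis))
    n = len(uniq)
    if n <= 1:
        return n
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    if n <= 200:
        for i in range(n):
            for j in range(i + 1, n):
                if _hamming1(uniq[i], uniq[j]):
                    union(i, j)
    else:
        # bucket by masked patterns: two UMIs at distance 1 share a pattern
        buckets: dict[str, list[int]] = defaultdict(list)
        L = len(uniq[0])
        for idx, u in enumerate(uniq):
            for p in range(L):
                buckets[u[:p] + "." + u[p + 1 :]].append(idx)
        for members in buckets.values():
            for other in members[1:]:
                union(members[0], other)
    return len({find(i) for i in range(n)})


# ---------------------------------------------------------------------------
# quantification


def load_gene_lookup(genes_tsv: str | Path) -> dict[str, str]:
    """tag -> gene_id mapping from a two-column (gene_id, tag) table."""
    df = pd.read_csv(genes_tsv, sep="\t", comment=None, names=["gene_id", "tag"], skiprows=1)
    return dict(zip(df["tag"], df["gene_id"]))


def quantify(
    r1_fastq: str | Path,
    r2_fastq: str | Path,
    wl: Whitelist,
    gene_lookup: Mapping[str, str],
    tag_length: int | None = None,
) -> tuple[dict[tuple[str, str], int], dict[str, int]]:
    """Count deduplicated molecules per (whitelist barcode, gene).

    For each read pair: the first 31 nt of R1 are matched against the
    whitelist (<=1 mismatch, unique); the first 9 nt of R2 are the UMI (8
    used); the following ``tag_length`` nt identify the gene by exact
    lookup.  Unassigned reads are counted by reason; assigned + unassigned
    reasons sum to the total.
    """
    if tag_length is None:
        tag_length = len(next(iter(gene_lookup)))
    groups: dict[tuple[str, str], set[str]] = defaultdict(set)
    stats = {"total": 0, "assigned": 0, "unassigned_cb": 0, "unassigned_gene": 0}
    for (_, r1), (_, r2) in zip(iter_fastq(r1_fastq), iter_fastq(r2_fastq)):
        stats["total"] += 1
        bc = match_barcode(r1[:CB_LENGTH], wl)
        if bc is None:
            stats["unassigned_cb"] += 1
            continue
        gene = gene_lookup.get(r2[UMI_EXTRACTED : UMI_EXTRACTED + tag_length])
        if gene is None:
            stats["unassigned_gene"] += 1
            continue
        stats["assigned"] += 1
        groups[(bc, gene)].add(r2[:UMI_USED])
    counts = {key: dedup_umis(umis) for key, umis in groups.items()}
    return counts, stats


# ---------------------------------------------------------------------------
# external count import / export (MatrixMarket triplets + list files)


def import_counts(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> dict[tuple[str, str], int]:
    """Ingest an externally produced barcode x gene sparse count matrix.

    The matrix is MatrixMarket COO with rows = barcodes, columns = genes,
    accompanied by one-per-line barcode and feature list files.
    """
    mat = scipy.io.mmread(str(mtx_path)).tocoo()
    barcodes = [l.strip() for l in Path(barcodes_path).read_text().splitlines() if l.strip()]
    features = [l.strip() for l in Path(features_path).read_text().splitlines() if l.strip()]
    if mat.shape != (len(barcodes), len(features)):
        raise QuantError(
            f"matrix shape {mat.shape} inconsistent with {len(barcodes)} barcodes "
            f"and {len(features)} features"
        )
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for i, j, v in zip(mat.row, mat.col, mat.data):
        counts[(barcodes[i], features[j])] += int(v)
    return dict(counts)


def export_counts(
    counts: Mapping[tuple[str, str], int],
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Inverse of :func:`import_counts` (sorted, deterministic layout)."""
    barcodes = sorted({bc for bc, _ in counts})
    features = sorted({g for _, g in counts})
    b_idx = {b: i for i, b in enumerate(barcodes)}
    f_idx = {f: j for j, f in enumerate(features)}
    rows = np.array([b_idx[bc] for bc, _ in counts], dtype=int)
    cols = np.array([f_idx[g] for _, g in counts], dtype=int)
    vals = np.array(list(counts.values()), dtype=int)
    mat = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(len(barcodes), len(features)))
    scipy.io.mmwrite(str(mtx_path), mat)
    Path(barcodes_path).write_text("".join(b + "\n" for b in barcodes))
    Path(features_path).write_text("".join(f + "\n" for f in features))


# ---------------------------------------------------------------------------
# GEM output


def write_gem(
    counts: Mapping[tuple[str, str], int],
    positions: Mapping[str, tuple[float, float]],
    calibration: ScaleCalibration,
    path: str | Path,
    provenance: str = "",
) -> None:
    """Write counts as a GEM file on the native coordinate grid.

    Columns are geneID, x, y, MIDCount; x and y are nm coordinates divided
    by the calibrated nm-per-unit and rounded to integers.  Multiple
    barcodes rounding to the same grid point have their molecule counts
    summed.  Every counted barcode must have a position.
    """
    missing = sorted({bc for bc, _ in counts if bc not in positions})
    if missing:
        raise QuantError(f"{len(missing)} counted barcodes lack coordinates, e.g. {missing[:3]}")
    agg: dict[tuple[str, int, int], int] = defaultdict(int)
    for (bc, gene), n in counts.items():
        x_nm, y_nm = positions[bc]
        x = int(round(x_nm / calibration.nm_per_unit))
        y = int(round(y_nm / calibration.nm_per_unit))
        agg[(gene, x, y)] += n
    with open(path, "w") as fh:
        fh.write("#FileFormat=GEMv0.1\n")
        fh.write(f"#nm_per_unit={calibration.nm_per_unit:.6f}\n")
        if provenance:
            fh.write(f"#provenance={provenance}\n")
        fh.write("geneID\tx\ty\tMIDCount\n")
        for (gene, x, y), n in sorted(agg.items()):
            fh.write(f"{gene}\t{x}\t{y}\t{n}\n")


def read_gem(path: str | Path) -> pd.DataFrame:
    """Read a GEM file into a DataFrame with geneID, x, y, MIDCount columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["geneID", "x", "y", "MIDCount"]
    if list(df.columns) != expected:
        raise QuantError(f"GEM columns {list(df.columns)} != {expected} in {path}")
    return df
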