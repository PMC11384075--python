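"""Square-bin aggregation and quality control of GEM data.

GEM records live on the native coordinate grid (~34.34 nm per unit).
Binning sums molecule counts over square bins anchored at the chip origin;
the standard bin edges are 728, 1456 and 2912 native units — 25, 50 and
100 um — conventionally called bin50, bin100 and bin200.  Bins with too
few detected genes are removed (75 / 250 / 500 genes respectively); the
mitochondrial fraction is reported but never used for filtering.
Surviving bins are normalized to 10,000 total counts and log1p
transformed for downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse

from .simulate import NM_PER_UNIT

__all__ = [
    "BIN_SIZES",
    "QcThresholds",
    "BinnedMatrix",
    "BinQcError",
    "bin_counts",
    "qc_filter",
    "normalize_log",
    "summarize",
]

#: Conventional bin level -> native-unit edge length.
BIN_SIZES = {"bin50": 728, "bin100": 1456, "bin200": 2912}


class BinQcError(ValueError):
    pass


@dataclass(frozen=True)
class QcThresholds:
    """Minimum detected genes per bin, keyed by native bin edge."""

    min_genes: Mapping[int, int] = field(
        default_factory=lambda: {728: 75, 1456: 250, 2912: 500}
    )

    def __post_init__(self) -> None:
        sizes = sorted(self.min_genes)
        values = [self.min_genes[s] for s in sizes]
        if any(v <= 0 for v in values):
            raise BinQcError("thresholds must be positive")
        if any(b < a for a, b in zip(values, values[1:])):
            raise BinQcError("thresholds must be non-decreasing with bin size")

    def for_bin(self, bin_size_native: int) -> int:
        try:
            return self.min_genes[bin_size_native]
        except KeyError:
            raise BinQcError(
                f"no QC threshold configured for bin size {bin_size_native}"
            ) from None


@dataclass
class BinnedMatrix:
    """Sparse bins x genes counts with the bin grid coordinates.

    Bin indices are ``floor(coordinate / bin_size_native)`` anchored at the
    chip origin, so bins nest exactly across levels (a 2912 bin is a 4 x 4
    block of 728 bins).
    """

    counts: scipy.sparse.csr_matrix  # (n_bins, n_genes)
    bins: pd.DataFrame  # columns bin_x, bin_y; row i <-> counts row i
    genes: list[str]
    bin_size_native: int
    nm_per_unit: float = NM_PER_UNIT

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_size_physical_um(self) -> float:
        return self.bin_size_native * self.nm_per_unit / 1000.0

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def genes_per_bin(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def umis_per_bin(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def bin_counts(
    gem: pd.DataFrame, bin_size_native: int, nm_per_unit: float = NM_PER_UNIT
) -> BinnedMatrix:
    """Aggregate GEM records into square bins (total counts conserved)."""
    if bin_size_native <= 0:
        raise BinQcError(f"bin size must be positive, got {bin_size_native}")
    bx = (gem["x"] // bin_size_native).to_numpy()
    by = (gem["y"] // bin_size_native).to_numpy()
    bins = pd.DataFrame({"bin_x": bx, "bin_y": by}).drop_duplicates().reset_index(drop=True)
    bin_key = {(x, y): i for i, (x, y) in enumerate(zip(bins["bin_x"], bins["bin_y"]))}
    genes = sorted(gem["geneID"].unique())
    gene_key = {g: j for j, g in enumerate(genes)}
    rows = np.fromiter((bin_key[(x, y)] for x, y in zip(bx, by)), count=len(gem), dtype=int)
    cols = gem["geneID"].map(gene_key).to_numpy()
    mat = scipy.sparse.coo_matrix(
        (gem["MIDCount"].to_numpy(), (rows, cols)), shape=(len(bins), len(genes))
    ).tocsr()
    return BinnedMatrix(
        counts=mat, bins=bins, genes=genes, bin_size_native=int(bin_size_native),
        nm_per_unit=nm_per_unit,
    )


def qc_filter(
    binned: BinnedMatrix,
    thresholds: QcThresholds | None = None,
    min_genes: int | None = None,
) -> tuple[BinnedMatrix, dict]:
    """Remove bins with too few detected genes (kept iff genes >= threshold).

    Counts of surviving bins are untouched.  The report also carries the
    mitochondrial-count percentage per kept bin (genes named ``mt-*``),
    which is informational only.
    """
    if min_genes is None:
        thresholds = thresholds or QcThresholds()
        min_genes = thresholds.for_bin(binned.bin_size_native)
    genes_per_bin = binned.genes_per_bin()
    keep = genes_per_bin >= min_genes
    if not keep.any():
        warnings.warn(
            f"all {binned.n_bins} bins fall below {min_genes} genes", stacklevel=2
        )
    filtered = BinnedMatrix(
        counts=binned.counts[keep],
        bins=binned.bins.loc[keep].reset_index(drop=True),
        genes=list(binned.genes),
        bin_size_native=binned.bin_size_native,
        nm_per_unit=binned.nm_per_unit,
    )
    mito_cols = [j for j, g in enumerate(binned.genes) if g.lower().startswith("mt-")]
    if mito_cols and filtered.n_bins:
        mito = np.asarray(filtered.counts[:, mito_cols].sum(axis=1)).ravel()
        totals = filtered.umis_per_bin()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    else:
        mito_pct = np.zeros(filtered.n_bins)
    report = {
        "min_genes": int(min_genes),
        "n_bins_in": int(binned.n_bins),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "removed_bins": binned.bins.loc[~keep].reset_index(drop=True),
        "median_mito_pct": float(np.median(mito_pct)) if len(mito_pct) else float("nan"),
    }
    return filtered, report


def normalize_log(
    binned: BinnedMatrix, target_sum: float = 10_000.0
) -> tuple[BinnedMatrix, int]:
    """Scale each bin to ``target_sum`` total counts, then apply log1p.

    Zero-total bins are left at zero and counted in the second return
    value.
    """
    totals = binned.umis_per_bin().astype(float)
    zero_bins = int((totals == 0).sum())
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    mat = binned.counts.tocsr().astype(float)
    mat = scipy.sparse.diags(scale) @ mat
    mat.data = np.log1p(mat.data)
    return replace(binned, counts=mat.tocsr()), zero_bins


def summarize(binned: BinnedMatrix) -> dict:
    """Per-bin medians of detected genes and total molecules."""
    if binned.n_bins == 0:
        return {"n_bins": 0, "median_genes": float("nan"), "median_umis": float("nan")}
    return {
        "n_bins": int(binned.n_bins),
        "bin_size_native": binned.bin_size_native,
        "bin_size_physical_um": binned.bin_size_physical_um,
        "median_genes": float(np.median(binned.genes_per_bin())),
        "median_umis": float(np.median(binned.umis_per_bin())),
        "total_counts": binned.total,
    }
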