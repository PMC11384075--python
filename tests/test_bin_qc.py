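"""Square binning, QC filtering, normalization and summaries."""

import numpy as np
import pandas as pd
import pytest

from novast.bin_qc import (
    BinQcError,
    QcThresholds,
    bin_counts,
    normalize_log,
    qc_filter,
    summarize,
)
from novast.simulate import NM_PER_UNIT


def _gem(rows):
    return pd.DataFrame(rows, columns=["geneID", "x", "y", "MIDCount"])


def test_bin_edges_floor_division():
    gem = _gem([("g", 0, 0, 1), ("g", 727, 727, 1), ("g", 728, 0, 1)])
    binned = bin_counts(gem, 728)
    assert binned.n_bins == 2
    first = binned.bins.iloc[0]
    assert (first["bin_x"], first["bin_y"]) == (0, 0)
    assert binned.counts[0].sum() == 2  # 0 and 727 share the first bin


def test_bin_counts_conservation_random_gem(rng):
    """Sparse binning equals a naive per-record accumulation oracle."""
    n = 2000
    gem = _gem(
        list(
            zip(
                rng.choice([f"g{i}" for i in range(20)], n),
                rng.integers(0, 30_000, n),
                rng.integers(0, 30_000, n),
                rng.integers(1, 6, n),
            )
        )
    )
    binned = bin_counts(gem, 728)
    assert binned.total == gem["MIDCount"].sum()
    naive: dict = {}
    for g, x, y, c in gem.itertuples(index=False):
        naive[(x // 728, y // 728, g)] = naive.get((x // 728, y // 728, g), 0) + c
    gene_idx = {g: j for j, g in enumerate(binned.genes)}
    for i, (bx, by) in enumerate(zip(binned.bins["bin_x"], binned.bins["bin_y"])):
        for g, j in gene_idx.items():
            assert binned.counts[i, j] == naive.get((bx, by, g), 0)


def test_bin_2912_equals_4x4_aggregation_of_728(rng):
    n = 3000
    gem = _gem(
        list(
            zip(
                rng.choice([f"g{i}" for i in range(15)], n),
                rng.integers(0, 40_000, n),
                rng.integers(0, 40_000, n),
                rng.integers(1, 5, n),
            )
        )
    )
    fine = bin_counts(gem, 728)
    coarse = bin_counts(gem, 2912)
    agg: dict = {}
    gi = {g: j for j, g in enumerate(fine.genes)}
    for i, (bx, by) in enumerate(zip(fine.bins["bin_x"], fine.bins["bin_y"])):
        key = (bx // 4, by // 4)
        row = fine.counts[i].toarray().ravel()
        agg[key] = agg.get(key, np.zeros(len(fine.genes))) + row
    assert coarse.genes == fine.genes
    for i, (bx, by) in enumerate(zip(coarse.bins["bin_x"], coarse.bins["bin_y"])):
        np.testing.assert_array_equal(
            coarse.counts[i].toarray().ravel(), agg[(bx, by)]
        )


def test_bin_size_physical():
    gem = _gem([("g", 0, 0, 1)])
    assert bin_counts(gem, 728).bin_size_physical_um == pytest.approx(25.0)
    assert bin_counts(gem, 2912).bin_size_physical_um == pytest.approx(100.0)
    # physical/native ratio is the constant calibration scale
    assert 728 * NM_PER_UNIT / 1000 == pytest.approx(25.0)


def test_bin_counts_invalid_size():
    with pytest.raises(BinQcError):
        bin_counts(_gem([("g", 0, 0, 1)]), 0)


def _matrix_with_gene_counts(genes_per_bin, bin_size=728):
    """One bin per entry, holding the requested number of distinct genes."""
    rows = []
    for b, k in enumerate(genes_per_bin):
        for g in range(k):
            rows.append((f"g{g}", b * bin_size, 0, 1))
    return bin_counts(_gem(rows), bin_size)


@pytest.mark.parametrize(
    "bin_size, threshold", [(728, 75), (1456, 250), (2912, 500)]
)
def test_qc_filter_thresholds_inclusive(bin_size, threshold):
    binned = _matrix_with_gene_counts([threshold - 1, threshold, threshold + 1], bin_size)
    filtered, report = qc_filter(binned)
    assert report["min_genes"] == threshold
    assert report["n_removed"] == 1 and report["n_kept"] == 2
    assert filtered.genes_per_bin().min() == threshold  # boundary kept


def test_qc_filter_preserves_surviving_counts():
    binned = _matrix_with_gene_counts([80, 10])
    filtered, _ = qc_filter(binned)
    kept = binned.genes_per_bin() >= 75
    np.testing.assert_array_equal(
        filtered.counts.toarray(), binned.counts[kept].toarray()
    )


def test_qc_filter_all_below_threshold_warns():
    binned = _matrix_with_gene_counts([5, 10])
    with pytest.warns(UserWarning, match="below"):
        filtered, report = qc_filter(binned)
    assert filtered.n_bins == 0 and report["n_removed"] == 2


def test_qc_filter_unknown_bin_size_errors():
    binned = _matrix_with_gene_counts([80], bin_size=500)
    with pytest.raises(BinQcError, match="no QC threshold"):
        qc_filter(binned)
    filtered, _ = qc_filter(binned, min_genes=10)  # explicit override works
    assert filtered.n_bins == 1


def test_qc_thresholds_validation():
    with pytest.raises(BinQcError):
        QcThresholds(min_genes={728: 100, 1456: 50})
    with pytest.raises(BinQcError):
        QcThresholds(min_genes={728: 0})


def test_qc_filter_reports_mito_percentage():
    rows = [("mt-co1", 0, 0, 25)] + [(f"g{i}", 0, 0, 1) for i in range(75)]
    binned = bin_counts(_gem(rows), 728)
    _, report = qc_filter(binned)
    assert report["median_mito_pct"] == pytest.approx(100 * 25 / 100)


def test_normalize_log_single_gene_bin():
    binned = bin_counts(_gem([("g", 0, 0, 5)]), 728)
    normalized, zero_bins = normalize_log(binned)
    assert zero_bins == 0
    assert normalized.counts[0, 0] == pytest.approx(np.log1p(10_000))


def test_normalize_log_totals_and_dense_oracle(rng):
    n = 500
    gem = _gem(
        list(
            zip(
                rng.choice([f"g{i}" for i in range(10)], n),
                rng.integers(0, 10_000, n),
                rng.integers(0, 10_000, n),
                rng.integers(1, 9, n),
            )
        )
    )
    binned = bin_counts(gem, 728)
    normalized, _ = normalize_log(binned)
    # pre-log totals are exactly 10,000 per bin
    prelog = np.expm1(normalized.counts.toarray())
    np.testing.assert_allclose(prelog.sum(axis=1), 10_000.0, rtol=1e-9)
    # dense per-entry recomputation
    dense = binned.counts.toarray().astype(float)
    expected = np.log1p(dense / dense.sum(axis=1, keepdims=True) * 10_000)
    np.testing.assert_allclose(normalized.counts.toarray(), expected, rtol=1e-9)


def test_summarize_medians():
    rows = [("g0", 0, 0, 1), ("g0", 728, 0, 1), ("g1", 728, 0, 1),
            ("g0", 1456, 0, 3), ("g1", 1456, 0, 3), ("g2", 1456, 0, 3)]
    binned = bin_counts(_gem(rows), 728)
    s = summarize(binned)
    assert s["n_bins"] == 3
    assert s["median_genes"] == 2.0
    assert s["median_umis"] == 2.0  # totals are {1, 2, 9}


def test_summarize_single_and_empty():
    single = bin_counts(_gem([("g", 10, 10, 7)]), 728)
    s = summarize(single)
    assert s["median_umis"] == 7.0 and s["median_genes"] == 1.0
    empty, _ = qc_filter(_matrix_with_gene_counts([1]), min_genes=10)
    assert summarize(empty)["n_bins"] == 0
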