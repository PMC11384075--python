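"""Tile selection, whitelist matching, UMI dedup and GEM output."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from novast.simulate import simulate_spatial_reads
from novast.spatial_quant import (
    CB_LENGTH,
    QuantError,
    Whitelist,
    build_whitelist,
    dedup_umis,
    export_counts,
    identify_tiles,
    import_counts,
    load_gene_lookup,
    match_barcode,
    quantify,
    read_gem,
    write_gem,
)
from novast.stitch import GlobalIndex, ScaleCalibration


# ---------------------------------------------------------------------------
# tile identification


def test_identify_tiles_selects_covered_tiles(chip_dir, chip_indexes, chip_selected):
    subsets = {ix.tile_id: ix.subset for ix in chip_indexes}
    selected, hits = identify_tiles(chip_dir / "spatial_R1.fastq", subsets, min_hits=5)
    assert selected == chip_selected
    assert all(hits[t] >= 5 for t in selected)


def test_identify_tiles_restricted_mask(chip_config, chip_truth, chip_indexes, tmp_path):
    """Reads drawn only from two tiles select exactly those tiles."""
    cfg = replace(
        chip_config, tissue_mask=chip_config.mask_from_tiles([1102, 1201]), n_molecules=2000
    )
    simulate_spatial_reads(cfg, chip_truth, tmp_path)
    subsets = {ix.tile_id: ix.subset for ix in chip_indexes}
    selected, _ = identify_tiles(tmp_path / "spatial_R1.fastq", subsets, min_hits=5)
    assert selected == [1102, 1201]


def test_identify_tiles_empty_input_errors(tmp_path, chip_indexes):
    empty = tmp_path / "r1.fastq"
    empty.write_text("")
    subsets = {ix.tile_id: ix.subset for ix in chip_indexes}
    with pytest.raises(QuantError, match="no reads"):
        identify_tiles(empty, subsets)


def test_identify_tiles_random_reads_no_selection(tmp_path, chip_indexes, rng):
    """Random 31-mers have ~n*|subset|/4^31 chance hits: none selected."""
    seqs = ["".join(rng.choice(list("ACGT"), 34)) for _ in range(1000)]
    fq = tmp_path / "r1.fastq"
    fq.write_text("".join(f"@r{i} 1\n{s}\n+\n{'I' * 34}\n" for i, s in enumerate(seqs)))
    subsets = {ix.tile_id: ix.subset for ix in chip_indexes}
    with pytest.raises(QuantError, match="no tile"):
        identify_tiles(fq, subsets, min_hits=1)


# ---------------------------------------------------------------------------
# whitelist


def test_whitelist_subset_of_selected_tiles(chip_whitelist, chip_truth, chip_selected):
    allowed = set()
    for tid in chip_selected:
        allowed.update(bc[:CB_LENGTH] for bc in chip_truth.well_barcodes[tid].astype(str))
    assert set(chip_whitelist.entries) <= allowed


def test_whitelist_trim_collisions_dropped():
    base = "CTCTTCCGATCT" + "A" * 19
    gi = GlobalIndex(
        barcodes=np.array([(base + "C").encode(), (base + "G").encode(),
                           ("CTCTTCCGATCT" + "C" * 20).encode()], dtype="S32"),
        x_nm=np.array([1.0, 2.0, 3.0]),
        y_nm=np.array([1.0, 2.0, 3.0]),
        tile_ids=np.array([1101, 1101, 1101], dtype=np.int32),
        calibration=ScaleCalibration(nm_per_unit=1.0),
    )
    wl = build_whitelist(gi, [1101])
    assert wl.collisions == 2  # both colliding 32-mers dropped
    assert len(wl) == 1


def test_whitelist_requires_selection(chip_global_index):
    with pytest.raises(QuantError):
        build_whitelist(chip_global_index, [])


# ---------------------------------------------------------------------------
# barcode matching: brute-force Hamming oracle


def _brute_force_match(cb: str, entries: list[str]) -> str | None:
    mat = np.frombuffer("".join(entries).encode(), dtype=np.uint8).reshape(len(entries), -1)
    q = np.frombuffer(cb.encode(), dtype=np.uint8)
    dist = (mat != q).sum(axis=1)
    if (dist == 0).any():
        return entries[int(np.argmax(dist == 0))]
    at1 = np.flatnonzero(dist == 1)
    return entries[int(at1[0])] if len(at1) == 1 else None


def test_match_barcode_agrees_with_brute_force(rng):
    """10^4 random queries against a 10^4-entry whitelist."""
    letters = np.array(list("ACGT"))
    entries = ["".join(r) for r in letters[rng.integers(0, 4, size=(10_000, CB_LENGTH))]]
    wl = Whitelist(entries={e: (0.0, 0.0) for e in entries})
    queries = []
    for i in range(10_000):
        base = entries[int(rng.integers(0, len(entries)))]
        kind = i % 4
        if kind == 0:
            q = base
        elif kind in (1, 2):
            n_sub = kind
            pos = rng.choice(CB_LENGTH, size=n_sub, replace=False)
            q = list(base)
            for p in pos:
                q[p] = letters[(letters.tolist().index(q[p]) + int(rng.integers(1, 4))) % 4]
            q = "".join(q)
        else:
            q = "".join(letters[rng.integers(0, 4, CB_LENGTH)])
        queries.append(q)
    for q in queries:
        assert match_barcode(q, wl) == _brute_force_match(q, entries), q


def test_match_barcode_ambiguous_is_unassigned():
    wl = Whitelist(entries={"A" * 31: (0, 0), "C" + "A" * 30: (0, 0)})
    # G+A*30 is at distance 1 from both entries
    assert match_barcode("G" + "A" * 30, wl) is None
    assert match_barcode("A" * 31, wl) == "A" * 31
    assert match_barcode("A" * 30 + "T", wl) == "A" * 31


def test_match_barcode_with_n_base():
    wl = Whitelist(entries={"A" * 31: (0, 0)})
    assert match_barcode("N" + "A" * 30, wl) == "A" * 31  # N counts as the 1 mismatch
    assert match_barcode("NN" + "A" * 29, wl) is None  # two mismatches


# ---------------------------------------------------------------------------
# UMI deduplication: connected-components oracle


def _dedup_oracle(umis):
    nx = pytest.importorskip("networkx")
    uniq = sorted(set(umis))
    g = nx.Graph()
    g.add_nodes_from(uniq)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            if sum(x != y for x, y in zip(a, b)) == 1:
                g.add_edge(a, b)
    return nx.number_connected_components(g)


@pytest.mark.parametrize(
    "umis, expected",
    [
        (["AAAAAAAA"] * 5, 1),
        (["AAAAAAAA", "AAAAAAAT"], 1),
        (["AAAAAAAA", "CCCCCCCC"], 2),
        (["AAAAAAAA", "AAAAAATT", "AAAAAAAT"], 1),  # chained through middle
        ([], 0),
    ],
)
def test_dedup_umis_examples(umis, expected):
    assert dedup_umis(umis) == expected


def test_dedup_umis_matches_oracle_on_random_multisets(rng):
    """10^3 random UMI multisets over a small alphabet (forces collisions)."""
    for _ in range(1000):
        n = int(rng.integers(1, 25))
        umis = ["".join(rng.choice(list("AC"), 8)) for _ in range(n)]
        assert dedup_umis(umis) == _dedup_oracle(umis)


def test_dedup_umis_bucket_path_matches_oracle(rng):
    """>200 distinct UMIs exercises the masked-pattern bucket path."""
    umis = ["".join(rng.choice(list("ACG"), 8)) for _ in range(400)]
    assert dedup_umis(umis) == _dedup_oracle(umis)


def test_dedup_umis_permutation_invariant_and_monotone(rng):
    umis = ["".join(rng.choice(list("AC"), 8)) for _ in range(12)]
    shuffled = list(rng.permutation(umis))
    assert dedup_umis(umis) == dedup_umis(shuffled)
    extra = "".join(rng.choice(list("ACGT"), 8))
    assert dedup_umis(umis + [extra]) <= dedup_umis(umis) + 1


# ---------------------------------------------------------------------------
# quantification


def test_quantify_error_free_matches_truth_exactly(chip_quantified, chip_reads):
    counts, stats = chip_quantified
    assert stats["assigned"] == stats["total"]
    truth_counts = (
        chip_reads.assign(cb=chip_reads["barcode"].str[:CB_LENGTH])
        .groupby(["cb", "gene_id"])["molecule_id"]
        .nunique()
    )
    assert sum(counts.values()) == int(truth_counts.sum())
    for (bc, gene), n in counts.items():
        assert truth_counts[(bc, gene)] == n


def test_quantify_conservation_of_reads(chip_quantified):
    _, stats = chip_quantified
    assert stats["assigned"] + stats["unassigned_cb"] + stats["unassigned_gene"] == stats["total"]


def test_quantify_two_cb_errors_unassigned(tmp_path):
    wl = Whitelist(entries={"A" * 31: (0.0, 0.0)})
    lookup = {"G" * 40: "gene_x"}
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    cb_2err = "CC" + "A" * 29 + "TTT"  # 34 nt, 2 errors in the first 31
    r1.write_text(f"@r0 1\n{cb_2err}\n+\n{'I' * 34}\n")
    r2.write_text(f"@r0 2\n{'T' * 9}{'G' * 40}{'A' * 42}\n+\n{'I' * 91}\n")
    counts, stats = quantify(r1, r2, wl, lookup)
    assert counts == {} and stats["unassigned_cb"] == 1


# ---------------------------------------------------------------------------
# matrix import/export and GEM


def test_import_export_roundtrip(tmp_path):
    counts = {("A" * 31, "gene_a"): 3, ("C" * 31, "gene_b"): 1, ("A" * 31, "gene_b"): 2}
    export_counts(counts, tmp_path / "m.mtx", tmp_path / "b.txt", tmp_path / "f.txt")
    back = import_counts(tmp_path / "m.mtx", tmp_path / "b.txt", tmp_path / "f.txt")
    assert back == counts


def test_import_counts_dimension_mismatch(tmp_path):
    counts = {("A" * 31, "gene_a"): 3}
    export_counts(counts, tmp_path / "m.mtx", tmp_path / "b.txt", tmp_path / "f.txt")
    (tmp_path / "b.txt").write_text("A" * 31 + "\n" + "C" * 31 + "\n")
    with pytest.raises(QuantError, match="inconsistent"):
        import_counts(tmp_path / "m.mtx", tmp_path / "b.txt", tmp_path / "f.txt")


def test_write_gem_roundtrip_and_conservation(tmp_path):
    cal = ScaleCalibration(nm_per_unit=2.0)
    counts = {("A" * 31, "g1"): 3, ("A" * 31, "g2"): 1, ("C" * 31, "g1"): 2}
    positions = {"A" * 31: (100.0, 200.0), "C" * 31: (500.0, 600.0)}
    path = tmp_path / "x.gem"
    write_gem(counts, positions, cal, path)
    gem = read_gem(path)
    assert gem["MIDCount"].sum() == sum(counts.values())
    assert len(gem) == 3
    row = gem[(gem["geneID"] == "g1") & (gem["x"] == 50)]
    assert row["y"].iloc[0] == 100  # nm / nm_per_unit, rounded


def test_write_gem_missing_position_errors(tmp_path):
    with pytest.raises(QuantError, match="lack coordinates"):
        write_gem(
            {("A" * 31, "g1"): 1},
            {},
            ScaleCalibration(nm_per_unit=1.0),
            tmp_path / "x.gem",
        )


def test_gene_lookup_roundtrip(chip_dir, chip_truth, chip_config):
    from novast.simulate import gene_catalog

    lookup = load_gene_lookup(chip_dir / "genes.tsv")
    catalog = gene_catalog(chip_config)
    assert lookup == dict(zip(catalog["tag"], catalog["gene_id"]))
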