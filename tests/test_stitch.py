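"""Scale calibration, grid expectations, offset recovery and stitching."""

from dataclasses import replace

import numpy as np
import pytest

from novast.fiducial_detect import TileFiducials, detect_tile_fiducials
from novast.hdmi_index import TileIndex, build_tile_index
from novast.simulate import SimConfig, simulate_flowcell
from novast.stitch import (
    ScaleCalibration,
    StitchError,
    apply_offsets,
    calibrate_scale,
    compute_tile_offsets,
    expected_centroid,
    read_global_index,
    write_global_index,
)


def test_calibrate_single_pair():
    cal = calibrate_scale([(25000.0, 728.0)])
    assert cal.nm_per_unit == pytest.approx(25000.0 / 728.0)


def test_calibrate_exact_multiples(rng):
    k = 12.345
    raw = rng.uniform(100, 10_000, size=8)
    cal = calibrate_scale(list(zip(k * raw, raw)))
    assert cal.nm_per_unit == pytest.approx(k, rel=1e-12)


def test_calibrate_noisy_matches_grid_search_oracle(rng):
    raw = rng.uniform(100, 10_000, size=20)
    nm = 34.34 * raw + rng.normal(0, 50, size=20)
    cal = calibrate_scale(list(zip(nm, raw)))
    ks = np.linspace(30, 40, 200_001)
    losses = ((nm[None, :] - ks[:, None] * raw[None, :]) ** 2).sum(axis=1)
    best = ks[losses.argmin()]
    assert cal.nm_per_unit == pytest.approx(best, abs=ks[1] - ks[0])


def test_calibrate_errors():
    with pytest.raises(StitchError):
        calibrate_scale([])
    with pytest.raises(StitchError):
        calibrate_scale([(25000.0, 0.0)])


def test_expected_centroid_grid():
    spacing = (6000.0, 6000.0)
    anchor = (100.0, 200.0)
    assert expected_centroid(0, 0, 1, spacing, anchor) == anchor
    s1 = expected_centroid(2, 0, 1, spacing, anchor)
    s2 = expected_centroid(2, 1, 2, spacing, anchor)
    assert s2[0] - s1[0] == pytest.approx(6000.0)  # adjacent swath
    assert s2[1] - s1[1] == pytest.approx(6000.0)  # even-swath stagger
    with pytest.raises(StitchError):
        expected_centroid(0, 6, 7, spacing, anchor)


def _fids(centroids):
    return {
        tid: TileFiducials(tile_id=tid, centroid=c, complete=c is not None)
        for tid, c in centroids.items()
    }


def test_offsets_zero_when_observed_matches_expected():
    c = (3000.0, 3000.0)
    fids = _fids({1101: c, 1102: c, 1201: c, 1202: c})
    offsets, excluded = compute_tile_offsets(fids, (6000.0, 6000.0))
    assert excluded == []
    # constant local centroids mean each tile sits exactly at its nominal
    # grid position: offsets equal the nominal origins (with even-swath stagger)
    assert (offsets[1101].dx, offsets[1101].dy) == (0.0, 0.0)
    assert (offsets[1102].dx, offsets[1102].dy) == (0.0, 6000.0)
    assert (offsets[1201].dx, offsets[1201].dy) == (6000.0, 6000.0)
    assert (offsets[1202].dx, offsets[1202].dy) == (6000.0, 12000.0)


def test_offset_recovers_apparent_content_shift():
    c = (3000.0, 3000.0)
    fids = _fids({1101: c, 1102: c, 1201: (c[0] + 7.0, c[1] - 3.0), 1202: c})
    offsets, _ = compute_tile_offsets(fids, (6000.0, 6000.0))
    assert offsets[1201].dx - 6000.0 == pytest.approx(-7.0)
    assert offsets[1201].dy - 6000.0 == pytest.approx(3.0)


def test_unresolved_tile_excluded():
    fids = _fids({1101: (0.0, 0.0), 1102: None})
    offsets, excluded = compute_tile_offsets(fids, (6000.0, 6000.0))
    assert excluded == [1102] and 1102 not in offsets


def test_second_pass_offsets_are_zero(rng):
    """Stitching is idempotent: recomputing offsets on corrected centroids
    yields exactly zero for every tile."""
    tids = [1101, 1102, 1103, 1201, 1202, 1203]
    fids = _fids({t: tuple(3000.0 + rng.normal(0, 20, 2)) for t in tids})
    offsets, _ = compute_tile_offsets(fids, (6000.0, 6000.0))
    corrected = _fids(
        {
            t: (fids[t].centroid[0] + offsets[t].dx, fids[t].centroid[1] + offsets[t].dy)
            for t in tids
        }
    )
    offsets2, _ = compute_tile_offsets(corrected, (6000.0, 6000.0))
    for t in tids:
        assert offsets2[t].dx == pytest.approx(0.0, abs=1e-9)
        assert offsets2[t].dy == pytest.approx(0.0, abs=1e-9)


def test_apply_offsets_identity_and_conservation(chip_indexes):
    cal = ScaleCalibration(nm_per_unit=1.0)
    offsets, _ = compute_tile_offsets(
        _fids({ix.tile_id: (0.0, 0.0) for ix in chip_indexes}), (0.0, 0.0)
    )
    gi = apply_offsets(chip_indexes, offsets, cal)
    assert len(gi) == sum(len(ix) for ix in chip_indexes)  # conservation
    first = chip_indexes[0]
    np.testing.assert_allclose(gi.x_nm[: len(first)], first.x.astype(float))
    np.testing.assert_allclose(gi.y_nm[: len(first)], first.y.astype(float))


def test_apply_offsets_missing_offset_errors(chip_indexes):
    with pytest.raises(StitchError, match="no offset"):
        apply_offsets(chip_indexes, {}, ScaleCalibration(nm_per_unit=1.0))


def test_stitching_is_rigid_per_tile(chip_indexes, chip_calibration):
    """Intra-tile pairwise distances are preserved up to the scale factor."""
    ix = chip_indexes[0]
    offsets, _ = compute_tile_offsets(
        _fids({j.tile_id: (10.0, -20.0) for j in chip_indexes}), (6000.0, 6000.0)
    )
    gi = apply_offsets(chip_indexes, offsets, chip_calibration)
    k = chip_calibration.nm_per_unit
    a, b = 0, len(ix) - 1
    d_local = np.hypot(float(ix.x[a]) - float(ix.x[b]), float(ix.y[a]) - float(ix.y[b]))
    d_global = np.hypot(gi.x_nm[a] - gi.x_nm[b], gi.y_nm[a] - gi.y_nm[b])
    assert d_global == pytest.approx(d_local * k, rel=1e-12)


def test_end_to_end_positions_match_truth(chip_global_index, chip_truth):
    """>=99 % of stitched records fall within 2 binned pixels of their true
    physical position (in practice far closer)."""
    gi = chip_global_index
    k = gi.calibration.nm_per_unit
    tol_nm = 2 * 25 * k
    ok = 0
    total = 0
    pos = {}
    for bc, x, y in zip(gi.barcodes, gi.x_nm, gi.y_nm):
        pos[bc] = (x, y)
    for tid in chip_truth.tile_ids:
        gx, gy = chip_truth.global_positions(tid)
        for bc, tx, ty in zip(chip_truth.well_barcodes[tid], gx * k, gy * k):
            px, py = pos[bc]
            total += 1
            if abs(px - tx) <= tol_nm and abs(py - ty) <= tol_nm:
                ok += 1
    assert ok / total >= 0.99


def test_jittered_offsets_recovered(tmp_path):
    """Per-tile frame errors are recovered within 2 binned pixels, and the
    calibrated scale from measured centroid spacings is within 0.5 %."""
    cfg = SimConfig(n_swaths=2, tiles_per_swath=2, seed=21, tile_jitter_sd=8.0)
    truth = simulate_flowcell(cfg, tmp_path)
    idxs = [build_tile_index(fq)[0] for fq in sorted((tmp_path / "hdmi").glob("*.fastq"))]
    fids = {ix.tile_id: detect_tile_fiducials(ix) for ix in idxs}
    offsets, _ = compute_tile_offsets(fids, (6000.0, 6000.0))
    anchor_err = None
    for tid, off in offsets.items():
        true_ox, true_oy = truth.tile_origins[tid]
        err = (off.dx - true_ox, off.dy - true_oy)
        if anchor_err is None:
            anchor_err = err  # common shift from anchoring on the first tile
        assert abs(err[0] - anchor_err[0]) <= 2 * 25
        assert abs(err[1] - anchor_err[1]) <= 2 * 25

    # scale recovery: physically known intra-tile fiducial spacings (the
    # microscopy measurement) paired with detected raw-unit spacings
    pairs = []
    for ix in idxs:
        true_local = truth.fiducial_centers[ix.tile_id]
        detected = np.array(
            [((c.x + 0.5) * 25, (c.y + 0.5) * 25) for c in fids[ix.tile_id].circles if c.kind == "outer"]
        )
        # match each true center to its nearest detection
        matched = np.array(
            [detected[np.hypot(*(detected - t).T).argmin()] for t in true_local]
        )
        for i in range(len(true_local)):
            for j in range(i + 1, len(true_local)):
                true_nm = np.hypot(*(true_local[i] - true_local[j])) * truth.nm_per_unit
                obs_raw = np.hypot(*(matched[i] - matched[j]))
                pairs.append((true_nm, obs_raw))
    cal = calibrate_scale(pairs)
    assert cal.nm_per_unit == pytest.approx(truth.nm_per_unit, rel=0.005)


def test_global_index_roundtrip(tmp_path, chip_global_index):
    path = tmp_path / "g.nvsg"
    write_global_index(chip_global_index, path)
    gi = read_global_index(path)
    assert np.array_equal(gi.barcodes, chip_global_index.barcodes)
    np.testing.assert_array_equal(gi.x_nm, chip_global_index.x_nm)
    np.testing.assert_array_equal(gi.tile_ids, chip_global_index.tile_ids)
    assert gi.calibration.nm_per_unit == chip_global_index.calibration.nm_per_unit
    assert gi.offsets == chip_global_index.offsets
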