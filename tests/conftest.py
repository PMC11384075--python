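"""Shared fixtures: one small simulated chip reused across the suite.

The chip is 2 swaths x 2 tiles with the default geometry (4 concentric
fiducial markers per tile, ~80 % occupancy) and an error-free spatial
library of 4000 molecules — large enough to exercise every pipeline stage,
small enough to simulate once per session.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from novast import fiducial_detect, hdmi_index, spatial_quant, stitch
from novast.simulate import SimConfig, simulate_flowcell, simulate_spatial_reads


@pytest.fixture(scope="session")
def chip_config() -> SimConfig:
    return SimConfig(n_swaths=2, tiles_per_swath=2, seed=11, n_molecules=4000)


@pytest.fixture(scope="session")
def chip_dir(tmp_path_factory, chip_config) -> Path:
    return tmp_path_factory.mktemp("chip")


@pytest.fixture(scope="session")
def chip_truth(chip_config, chip_dir):
    return simulate_flowcell(chip_config, chip_dir)


@pytest.fixture(scope="session")
def chip_reads(chip_config, chip_truth, chip_dir):
    return simulate_spatial_reads(chip_config, chip_truth, chip_dir)


@pytest.fixture(scope="session")
def chip_indexes(chip_truth, chip_dir, chip_reads) -> list[hdmi_index.TileIndex]:
    return [
        hdmi_index.build_tile_index(fq)[0]
        for fq in sorted((chip_dir / "hdmi").glob("*.fastq"))
    ]


@pytest.fixture(scope="session")
def chip_fiducials(chip_indexes) -> dict[int, fiducial_detect.TileFiducials]:
    fids = {ix.tile_id: fiducial_detect.detect_tile_fiducials(ix) for ix in chip_indexes}
    fids, _ = fiducial_detect.interpolate_missing(fids)
    return fids


@pytest.fixture(scope="session")
def chip_calibration() -> stitch.ScaleCalibration:
    return stitch.calibrate_scale([(25000.0, 728.0)])


@pytest.fixture(scope="session")
def chip_global_index(chip_indexes, chip_fiducials, chip_config, chip_calibration):
    offsets, excluded = stitch.compute_tile_offsets(
        chip_fiducials,
        (float(chip_config.tile_width), float(chip_config.tile_height)),
    )
    assert not excluded
    return stitch.apply_offsets(chip_indexes, offsets, chip_calibration)


@pytest.fixture(scope="session")
def chip_selected(chip_dir, chip_indexes) -> list[int]:
    subsets = {ix.tile_id: ix.subset for ix in chip_indexes}
    selected, _ = spatial_quant.identify_tiles(
        chip_dir / "spatial_R1.fastq", subsets, min_hits=5
    )
    return selected


@pytest.fixture(scope="session")
def chip_whitelist(chip_global_index, chip_selected) -> spatial_quant.Whitelist:
    return spatial_quant.build_whitelist(chip_global_index, chip_selected)


@pytest.fixture(scope="session")
def chip_quantified(chip_dir, chip_whitelist):
    lookup = spatial_quant.load_gene_lookup(chip_dir / "genes.tsv")
    return spatial_quant.quantify(
        chip_dir / "spatial_R1.fastq", chip_dir / "spatial_R2.fastq", chip_whitelist, lookup
    )


@pytest.fixture(scope="session")
def noisy_reads(chip_config, chip_truth, tmp_path_factory):
    """Spatial library on the same chip with 0.5 % per-base substitutions."""
    out = tmp_path_factory.mktemp("noisy")
    cfg = replace(chip_config, error_rate=0.005)
    reads = simulate_spatial_reads(cfg, chip_truth, out)
    return out, reads


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
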