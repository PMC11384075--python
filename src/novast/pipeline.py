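"""End-to-end pipeline orchestration with a plain-text config and manifest.

Stages run in dependency order:

    index -> fiducials -> stitch -> select-tiles -> whitelist ->
    quantify | import -> gem -> bin/qc

Each stage records its inputs' SHA-256 hashes and its outputs in a JSON
manifest; rerunning with unchanged inputs skips completed stages, and a
repeated run with the same config and seed reproduces the manifest
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import bin_qc, fiducial_detect, hdmi_index, spatial_quant, stitch

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("novast")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (one YAML document)."""

    hdmi_fastq_dir: Path
    spatial_r1: Path
    spatial_r2: Path
    out_dir: Path
    genes_tsv: Path | None = None  # internal quantification path
    external_counts: dict | None = None  # {mtx, barcodes, features}
    barcode_template: str = hdmi_index.DEFAULT_TEMPLATE
    excluded_tiles: list[int] = field(default_factory=list)
    subset_size: int = 10_000
    fiducial: dict = field(default_factory=dict)  # FiducialParams overrides
    calibration_spacings: list[tuple[float, float]] = field(
        default_factory=lambda: [(25000.0, 728.0)]
    )
    tile_spacing_units: tuple[float, float] = (6000.0, 6000.0)
    swath_offset_axis: str = "y"
    identify_n_reads: int = 1_000_000
    identify_min_hits: int = 10
    bin_sizes: list[int] = field(default_factory=lambda: [728, 1456, 2912])
    qc_min_genes: dict[int, int] = field(
        default_factory=lambda: {728: 75, 1456: 250, 2912: 500}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("hdmi_fastq_dir", "spatial_r1", "spatial_r2"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"{name} does not exist: {p}")
        if self.genes_tsv is None and self.external_counts is None:
            raise PipelineError("either genes_tsv (internal) or external_counts must be set")
        if self.external_counts is not None:
            for key in ("mtx", "barcodes", "features"):
                if key not in self.external_counts:
                    raise PipelineError(f"external_counts missing {key!r}")

    def fiducial_params(self) -> fiducial_detect.FiducialParams:
        kwargs = dict(self.fiducial)
        for key in ("outer_radius_range", "inner_radius_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return fiducial_detect.FiducialParams(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("hdmi_fastq_dir", "spatial_r1", "spatial_r2", "out_dir", "genes_tsv"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    if "calibration_spacings" in raw:
        raw["calibration_spacings"] = [tuple(p) for p in raw["calibration_spacings"]]
    if "tile_spacing_units" in raw:
        raw["tile_spacing_units"] = tuple(raw["tile_spacing_units"])
    if "qc_min_genes" in raw:
        raw["qc_min_genes"] = {int(k): int(v) for k, v in raw["qc_min_genes"].items()}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_fresh(self, name: str, inputs: Sequence[Path]) -> bool:
        """True if the stage already ran on identical inputs and outputs exist."""
        st = self.data["stages"].get(name)
        if st is None:
            return False
        if st.get("inputs") != {str(p): _sha256(p) for p in inputs}:
            return False
        return all(Path(o).exists() for o in st.get("outputs", {}))

    def record(
        self, name: str, inputs: Sequence[Path], outputs: Sequence[Path], info: Mapping
    ) -> None:
        self.data["stages"][name] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "info": dict(info),
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["config"] = {
        "seed": config.seed,
        "barcode_template": config.barcode_template,
        "excluded_tiles": sorted(config.excluded_tiles),
        "calibration_spacings": [list(p) for p in config.calibration_spacings],
        "tile_spacing_units": list(config.tile_spacing_units),
        "bin_sizes": list(config.bin_sizes),
        "qc_min_genes": {str(k): v for k, v in sorted(config.qc_min_genes.items())},
    }

    try:
        ctx: dict = {}
        _stage_index(config, manifest, ctx)
        _stage_fiducials(config, manifest, ctx)
        _stage_stitch(config, manifest, ctx)
        _stage_select_tiles(config, manifest, ctx)
        _stage_whitelist(config, manifest, ctx)
        _stage_counts(config, manifest, ctx)
        _stage_gem(config, manifest, ctx)
        _stage_bins(config, manifest, ctx)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise PipelineError(f"stage {ctx.get('stage', '?')!r} failed: {exc}") from exc
    return manifest.data


def _fastq_files(config: RunConfig) -> list[Path]:
    files = sorted(Path(config.hdmi_fastq_dir).glob("*.fastq")) + sorted(
        Path(config.hdmi_fastq_dir).glob("*.fastq.gz")
    )
    if not files:
        raise PipelineError(f"no FASTQ files in {config.hdmi_fastq_dir}")
    return files


def _index_dir(config: RunConfig) -> Path:
    return Path(config.out_dir) / "indexes"


def _stage_index(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "index"
    fastqs = _fastq_files(config)
    idx_dir = _index_dir(config)
    pattern = hdmi_index.BarcodePattern(template=config.barcode_template)
    if manifest.stage_fresh("index", fastqs):
        log.info("index: up to date, skipping")
        ctx["indexes"] = [
            hdmi_index.read_index(p, config.subset_size)
            for p in sorted(idx_dir.glob("tile_*.nvst"))
            if not p.name.endswith(".subset.nvst")
        ]
        return
    idx_dir.mkdir(parents=True, exist_ok=True)
    indexes, totals = [], {"total": 0, "valid": 0, "invalid": 0}
    excluded = set(config.excluded_tiles)
    for fq in fastqs:
        index, stats = hdmi_index.build_tile_index(
            fq, pattern, subset_size=config.subset_size
        )
        if index.tile_id in excluded:
            log.info("index: tile %d excluded by config", index.tile_id)
            continue
        indexes.append(index)
        for k in totals:
            totals[k] += stats[k]
    outputs = hdmi_index.write_indexes(indexes, idx_dir)
    outputs += [idx_dir / f"tile_{ix.tile_id}.subset.nvst" for ix in indexes]
    log.info(
        "index: %d tiles, %d/%d valid reads", len(indexes), totals["valid"], totals["total"]
    )
    manifest.record("index", fastqs, outputs, {"tiles": len(indexes), **totals})
    ctx["indexes"] = indexes


def _stage_fiducials(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "fiducials"
    params = config.fiducial_params()
    fids = {}
    for ix in ctx["indexes"]:
        fids[ix.tile_id] = fiducial_detect.detect_tile_fiducials(ix, params)
    fids, unresolved = fiducial_detect.interpolate_missing(fids)
    report = Path(config.out_dir) / "fiducials.tsv"
    fiducial_detect.write_fiducial_report(fids, report)
    n_complete = sum(f.complete for f in fids.values())
    log.info(
        "fiducials: %d/%d tiles complete, %d unresolved", n_complete, len(fids), len(unresolved)
    )
    if unresolved:
        log.warning("fiducials: unresolved tiles %s excluded downstream", unresolved)
    manifest.record(
        "fiducials", [], [report],
        {"complete": n_complete, "tiles": len(fids), "unresolved": unresolved},
    )
    ctx["fiducials"] = fids


def _stage_stitch(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "stitch"
    calibration = stitch.calibrate_scale(config.calibration_spacings)
    offsets, excluded = stitch.compute_tile_offsets(
        ctx["fiducials"], config.tile_spacing_units, offset_axis=config.swath_offset_axis
    )
    kept = [ix for ix in ctx["indexes"] if ix.tile_id in offsets]
    gi = stitch.apply_offsets(kept, offsets, calibration)
    path = Path(config.out_dir) / "global_index.nvsg"
    stitch.write_global_index(gi, path)
    log.info(
        "stitch: %d records over %d tiles at %.4f nm/unit (%d duplicate-barcode records)",
        len(gi), len(offsets), calibration.nm_per_unit, gi.duplicate_barcodes,
    )
    manifest.record(
        "stitch", [], [path],
        {
            "nm_per_unit": calibration.nm_per_unit,
            "records": len(gi),
            "excluded_tiles": excluded,
            "duplicate_barcodes": gi.duplicate_barcodes,
        },
    )
    ctx["global_index"] = gi


def _stage_select_tiles(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "select-tiles"
    subsets = {ix.tile_id: ix.subset for ix in ctx["indexes"]}
    selected, hits = spatial_quant.identify_tiles(
        config.spatial_r1, subsets, config.identify_n_reads, config.identify_min_hits
    )
    log.info("select-tiles: %d tiles under tissue: %s", len(selected), selected)
    manifest.record(
        "select-tiles", [Path(config.spatial_r1)], [],
        {"selected": selected, "hits": {str(k): v for k, v in sorted(hits.items())}},
    )
    ctx["selected"] = selected


def _stage_whitelist(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "whitelist"
    wl = spatial_quant.build_whitelist(ctx["global_index"], ctx["selected"])
    path = Path(config.out_dir) / "whitelist.txt"
    with open(path, "w") as fh:
        for bc in sorted(wl.entries):
            fh.write(bc + "\n")
    log.info("whitelist: %d barcodes (%d trim collisions dropped)", len(wl), wl.collisions)
    manifest.record(
        "whitelist", [], [path], {"entries": len(wl), "collisions": wl.collisions}
    )
    ctx["whitelist"] = wl


def _stage_counts(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "quantify"
    if config.external_counts is not None:
        ext = {k: Path(v) for k, v in config.external_counts.items()}
        counts = spatial_quant.import_counts(ext["mtx"], ext["barcodes"], ext["features"])
        known = {bc for bc, _ in counts if bc in ctx["whitelist"].entries}
        dropped = {k: v for k, v in counts.items() if k[0] not in known}
        counts = {k: v for k, v in counts.items() if k[0] in known}
        log.info(
            "import: %d entries kept, %d dropped (barcode not in whitelist)",
            len(counts), len(dropped),
        )
        info = {"mode": "import", "entries": len(counts), "dropped": len(dropped)}
        inputs = list(ext.values())
    else:
        lookup = spatial_quant.load_gene_lookup(config.genes_tsv)
        counts, stats = spatial_quant.quantify(
            config.spatial_r1, config.spatial_r2, ctx["whitelist"], lookup
        )
        log.info("quantify: %s", stats)
        info = {"mode": "internal", **stats}
        inputs = [Path(config.spatial_r1), Path(config.spatial_r2), Path(config.genes_tsv)]
    manifest.record("quantify", inputs, [], info)
    ctx["counts"] = counts


def _stage_gem(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "gem"
    gi = ctx["global_index"]
    path = Path(config.out_dir) / "counts.gem"
    spatial_quant.write_gem(
        ctx["counts"], ctx["whitelist"].entries, gi.calibration, path,
        provenance=f"tiles={','.join(map(str, ctx['selected']))}",
    )
    total = sum(ctx["counts"].values())
    log.info("gem: %d records, %d molecules", len(ctx["counts"]), total)
    manifest.record("gem", [], [path], {"molecules": total})
    ctx["gem_path"] = path


def _stage_bins(config: RunConfig, manifest: _Manifest, ctx: dict) -> None:
    ctx["stage"] = "bin"
    gem = spatial_quant.read_gem(ctx["gem_path"])
    thresholds = bin_qc.QcThresholds(min_genes=dict(config.qc_min_genes))
    qc_rows = []
    outputs = []
    nm_per_unit = ctx["global_index"].calibration.nm_per_unit
    for size in config.bin_sizes:
        binned = bin_qc.bin_counts(gem, size, nm_per_unit)
        filtered, report = bin_qc.qc_filter(binned, thresholds)
        normalized, zero_bins = bin_qc.normalize_log(filtered)
        summary = bin_qc.summarize(filtered)
        qc_rows.append({**summary, **{k: report[k] for k in ("min_genes", "n_kept", "n_removed")}})
        prefix = Path(config.out_dir) / f"bin_{size}"
        spatial_quant.export_counts(
            _matrix_to_counts(filtered),
            f"{prefix}.mtx", f"{prefix}.bins.txt", f"{prefix}.genes.txt",
        )
        outputs += [Path(f"{prefix}.mtx"), Path(f"{prefix}.bins.txt"), Path(f"{prefix}.genes.txt")]
        log.info("bin %d: %s (zero-total bins after QC: %d)", size, qc_rows[-1], zero_bins)
    qc_path = Path(config.out_dir) / "qc_report.tsv"
    import pandas as pd

    pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False)
    manifest.record("bin", [ctx["gem_path"]], outputs + [qc_path], {"levels": list(config.bin_sizes)})


def _matrix_to_counts(binned: bin_qc.BinnedMatrix) -> dict[tuple[str, str], int]:
    coo = binned.counts.tocoo()
    return {
        (f"{binned.bins['bin_x'][i]}_{binned.bins['bin_y'][i]}", binned.genes[j]): int(v)
        for i, j, v in zip(coo.row, coo.col, coo.data)
    }
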