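# Methods

This note documents the models, parameter choices and numerical decisions
behind `novast`, and what the bundled simulator does and does not emulate.

## Flow-cell geometry

Nano-wells sit on a hexagonal lattice; each lattice site owns a rhombic
unit cell of area (√3/2)·p² for pitch p. Packing density is the
reciprocal of that area (wells per 100 µm² = 10⁸ nm² / cell area).
*Dead space* is defined **per lattice site**: unit-cell area minus the
well-opening circle area. Under this definition the S4 geometry
(p = 625 nm, d = 300 nm) has 267,606 nm² dead space per site and the
X-25B geometry (p = 399 nm, d = 280 nm) 76,297 nm², a 3.51× reduction.
The alternative area-fraction definition (dead fraction of the unit cell)
would give only ≈1.4× and is not used. Note the closed form at the S4
pitch gives ≈296 wells per 100 µm², not the ≈350 sometimes quoted for
this pattern; the package reports the closed-form value.

A Monte-Carlo oracle (uniform points over a p × √3p rectangle containing
exactly two lattice sites) cross-checks the closed form in the tests.

## Coordinate system and calibration

All read-name coordinates are "raw units". The physical scale is
calibrated, not assumed: nm-per-unit is the least-squares slope through
the origin over measured (nm, raw-unit) fiducial-spacing pairs. The
default single pair (25,000 nm, 728 units) encodes the convention that a
728-unit spatial bin measures 25 µm, i.e. 34.34 nm per raw unit. The
simulator uses the same scale so its ground truth is expressed in the
units the pipeline reconstructs.

## Simulator

The simulator generates, per tile, the intersection of one ideal global
hexagonal lattice with the tile's imaging frame. What varies between
tiles is the frame placement: per-tile frame errors (`tile_jitter_sd`,
`tile_shifts`) displace the frame, so fiducial marks appear shifted in
local read coordinates while wells keep their ideal physical positions —
exactly the situation stitching must correct. Each lattice site
independently receives a unique random barcode with probability
`unique_occupancy` (default 0.80, matching the ~80 % unique-well rate of
real flow cells); the remaining wells are simulated as empty, a
simplification — real non-unique wells carry mixed clusters whose reads
fail validation rather than being absent. Barcode uniqueness is enforced
chip-wide by rejection sampling over the 4¹⁵·3⁵ ≈ 2.6·10¹¹-element
degenerate space.

Fiducial markers are barcode-free voids at fixed intra-tile positions
(quadrant centers for the default 4 markers/tile): a filled disk of the
inner radius plus a thin ring at the outer radius, the concentric-circle
pattern the detector expects. A 1-unit guard band on the void edges keeps
integer rounding of local coordinates from re-populating a void.

Default geometry: 6 × 6 tiles of 6000 × 6000 raw units (~206 µm) — a
deliberately scaled-down chip (real tiles are ~30× larger) chosen so a
full chip holds ~4M wells and simulates in seconds-to-minutes. The well
pitch default is 15 raw units (~515 nm), slightly denser than the
physical 625 nm: at the physical pitch a density-image pixel holds only
2–3 lattice sites, and the resulting integer count distribution puts
typical occupancy at ~45 % of the per-image maximum, which the fixed
128 threshold would misclassify as void. Real cluster data evidently has
a smoother per-pixel distribution; 15 units (~3 sites/pixel) reproduces
the clean tissue/void separation the standard constants assume.
Per-tile FASTQ records are emitted in shuffled (spatially mixed) order,
as clusters come off an instrument; the deterministic first-10,000-read
identification subsets rely on this.

The spatial library samples molecules uniformly from occupied wells
inside the tissue mask (default: the central quarter of the chip; masks
are unions of rectangles). Each molecule gets a uniform random gene, a
random 9-nt UMI, and 1 + Poisson(μ−1) duplicate reads (default mean 3
reads/molecule, i.e. ~33 % unique reads, the deep-sequencing regime).
R1 is the 32-nt barcode padded to 34 nt; R2 is UMI (9 nt) + a 40-nt
gene tag + random filler to 91 nt. Substitution errors are applied
independently per base; no indels, no quality-score model (qualities are
constant 'I'), no optical/chemistry effects, no index reads. Gene tags
are unique random 40-mers, which makes the internal quantifier's
exact-tag gene assignment valid by construction — real-read gene
assignment belongs to an external aligner whose matrix is merged via the
import path. Passing tests therefore demonstrate the pipeline's
reconstruction logic, not robustness to alignment ambiguity, chimeras or
indel-rich data.

## Barcode indexing

Reads are validated position-by-position against a 32-symbol IUPAC
template, default `CTCTTCCGATCT` + `NNVNNVNNVNNVNNVNNNNN` (V = A/C/G,
B = C/G/T, N = any); the orientation (constant block first) follows the
oligo design read through reverse-complement demultiplexing and is
configurable since deposited data could differ. No base-quality
filtering is applied. Indexes are fixed-layout binary: header
(magic `NVST`, version, tile id, record count) then 16-byte records
(2-bit-packed barcode in a u64, two u32 coordinates), little-endian —
lossless for ACGT barcodes and round-trip-tested. The per-tile
identification subset is the first 10,000 valid reads: deterministic by
choice, and spatially unbiased when read order is mixed.

Tile ids follow the 4-digit sequencer convention (surface, swath 1–6,
two-digit row), isolated behind `parse_read_name`.

## Fiducial detection

Per tile: occupancy is binned at 25 raw units/pixel and max-normalized
to 255; the image is inverted (voids bright), denoised with non-local
means at strength h = 100 (patch 5, search radius 6, on the 0–255
scale), and binarized at 128. The binary void pattern itself is the
evidence image for a circle Hough transform run separately over the
outer (40–80 px) and inner (15–30 px) radius ranges, radius step 2.
Accepted peaks need a normalized response ≥ 0.45; around each accepted
center a neighborhood of one maximal-range radius is suppressed —
duplicate responses of one marker fall within its own radius, while
distinct markers are farther apart. Because thick rings and filled
disks produce a *plateau* of saturated responses around the true center,
the reported center is the center of mass of the plateau (responses
within 0.02 of the peak), which removes the ~1.4 px corner bias of a
plain argmax. Centers map back to raw units at pixel midpoints
((px + 0.5) · 25).

A tile is *complete* when both ranges yield the expected marker count
(default 4 each, 8 circles total); its centroid is the combined mean of
all 8 centers (per-class means are also reported). Missing centroids are
interpolated as the mean of available centroids of neighbors at grid
distance 1, valid because intra-tile fiducial placement is constant.
On simulated chips the detected centroid is within ~0.3 binned pixels of
truth.

## Stitching

Per-tile correction is translation-only: offset = expected centroid −
observed centroid, with the expected grid anchored at the top-left
tile's observed centroid (so that tile gets offset zero) and
even-numbered swaths staggered by one tile spacing (axis configurable;
default along tile rows). Rotation and shear within a tile are assumed
negligible. Stitching is idempotent — recomputing offsets on corrected
centroids yields exactly zero — and rigid per tile. Global coordinates
are (local + offset) · nm-per-unit; records are conserved, and barcodes
seen in more than one tile are counted and reported rather than dropped.
Tiles whose centroid cannot be detected or interpolated are excluded and
listed.

## Quantification

Tissue-covered tiles are those whose 10,000-read subset shares at least
`min_hits` (default 10) distinct exact 31-nt barcodes with the first 10⁶
spatial R1 reads; chance hits for random 31-mers are ~n·10⁴/4³¹ ≪ 1.
The whitelist holds 31-nt-trimmed barcodes of the selected tiles;
trim collisions are dropped on both sides and counted. Matching allows
at most one mismatch with unique resolution: exact first, then the 93
single-substitution variants; two or more candidate entries leave the
read unassigned (deterministic and conservative). A non-ACGT base simply
consumes the one allowed mismatch.

UMIs: 9 bases are extracted from R2 but 8 are used for deduplication,
following the quantifier parameter set (barcode length 31, UMI offset
32, length 8) rather than the 9-base extraction note; the 9th base is
retained in the read but ignored. R1 is truncated to 31 nt for matching
(the 32nd base is covered by the trim-collision handling). Deduplication
merges UMIs within Hamming distance 1 into connected components and
counts components ("1MM_All" semantics read as an undirected graph; no
count-weighted directionality). The GEM output is tab-separated
geneID/x/y/MIDCount with `#` header lines; x, y are nm coordinates
divided by nm-per-unit and rounded to the native integer grid.

## Binning and QC

Bins are squares of 728/1456/2912 native units (25/50/100 µm), indices
anchored at the chip origin (floor division), so levels nest exactly:
one 2912 bin is a 4 × 4 block of 728 bins, and counts are conserved.
QC keeps a bin iff its detected-gene count is ≥ the threshold
(75/250/500 by level; the boundary is kept). Mitochondrial percentage
(genes named `mt-*`) is reported but never filters. Normalization scales
each bin to 10,000 total counts then applies natural log1p; zero-total
bins stay zero and are counted. Downstream HVG selection, regression,
scaling, PCA and clustering are standard toolkit territory and out of
scope here.

## Registration

The stain-to-spatial mapping is a full 6-parameter affine fitted by
linear least squares on landmark pairs; ≥3 non-collinear pairs are
required (rank check with a scale-aware tolerance). Residuals are
returned per pair; they are invariant under a common rigid motion of
both point sets. No automatic landmark detection: pairs are provided in
a 4-column text file, as they come from interactive selection.

## Pipeline orchestration

One YAML config drives the stage sequence (index → fiducials → stitch →
select-tiles → whitelist → quantify/import → gem → bin). A JSON manifest
records input/output SHA-256 hashes and per-stage counts; a rerun with
unchanged inputs skips completed stages, and identical config + seed
reproduces the manifest byte-identically. Any stage failure aborts with
the stage name. The `novast` command exposes the stages plus the
simulator and the geometry calculator.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own trade-off between statistical power and a
single-CPU run: the shared test chip is 2 × 2 tiles (~460k wells, 4000
molecules); the acceptance script uses a 6 × 6-tile chip (~4.1M wells)
for fiducial recovery, ten jittered 2 × 2 chips for stitching recovery,
10⁴ × 10⁴ queries for the barcode-matching oracle, 10³ multisets for the
UMI oracle, and one 2 × 2 chip with 20,000 molecules (error rates 0 and
0.005) for the end-to-end checks.

## Known limitations

- Translation-only tile correction; real chips with measurable intra-tile
  rotation would leave residuals the model cannot absorb.
- The internal quantifier's exact-tag gene lookup is a stand-in for
  alignment; real data should come in through the matrix-import path.
- Fiducial radius estimates are biased toward the lower end of each
  search range for filled disks (the plateau spans radii); only centers,
  which are unbiased, feed the centroid.
- Non-unique wells are modeled as empty rather than as mixed clusters.
- Cross-surface (top/bottom glass) co-registration is out of scope; each
  chip is one surface.
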