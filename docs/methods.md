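# Methods

## The measurement model

Deterministic barcoding in tissue encodes position by chemistry: DNA
barcodes are ligated to cDNA through microfluidic channels pressed onto the
section, first horizontally, then vertically. A transcript therefore ends up
tagged with a y-barcode (its horizontal channel / row), an x-barcode (its
vertical channel / column), a well barcode (z) from the
reverse-transcription primer identifying which of the nine sections it came
from, and a random unique molecular identifier (UMI). The unit of
measurement is the spot: the square intersection of one horizontal and one
vertical channel (50 µm side, 100 µm center-to-center on the production
chip). This package reconstructs, for each spot and gene, the number of
distinct tagged molecules, and places each spot into microscope-image
coordinates.

Axis convention (fixed here, configurable via `ChipLayout.swap_xy_axes`
because the chemistry itself does not dictate it): ligation round #1
(horizontal channels) encodes the row index y; round #2 (vertical channels)
encodes the column index x. Coordinates use the image convention — origin
at the top-left of each capture area, x rightward, y downward, µm units,
0-based indices. A spot center sits at
`section_origin + index * pitch + channel_width / 2` per axis.

The production chip has 38 channels per axis of which the two outermost
carry fluorescent alignment marker instead of barcodes. We model both
totals explicitly: 38 × 38 = 1444 intersections exist physically per
capture area, 36 × 36 = 1296 of them are barcoded (`Spot.is_barcoded`).
The scan-area identity `n_areas * (n_barcoded_channels * pitch)^2` gives
116.64 mm² for nine areas, a 4.6656-fold increase over the 25 mm²
single-section reference chip (4.6656 truncates to the conventionally
quoted 4.66).

## Demultiplexing

Read 2 is cut into segments by a configurable `ReadLayout` (defaults:
10 nt UMI, three 8 nt barcodes in the order UMI–x–linker–y–linker–z;
linker lengths are free parameters because the exact read-2 architecture is
an experimental design choice). Each barcode is matched against the legend
by Hamming distance with at most `max_hamming` mismatches (default 1).
Matching is strict: a read resolves only when exactly one legend entry
attains the minimal distance; ties are rejected even between entries that
map to the same value, which keeps the decision identical to an exhaustive
minimum-distance search (the property the tests verify against a
brute-force oracle). Hamming rather than edit distance keeps fixed-length
barcode matching deterministic and O(1) via a precomputed single-mismatch
table. Reads failing x or y (or z where the layout defines it) are
discarded with a per-axis status; statuses partition the input
(`valid + short + invalid_x + invalid_y + invalid_z + crosstalk = total`).

Genome alignment is deliberately out of scope: read 1 is assigned by unique
exact match of its first 30 nt against a toy transcript set (FASTA headers
`gene|transcript|region`), with ambiguous or absent prefixes left
unassigned, and intronic records counted only when `include_intronic` is
on. Real data can instead supply a pre-tagged read table
(read_id → gene, region) produced by any aligner.

UMI collapsing is single-linkage clustering of the distinct UMIs of each
(spot, gene) group at Hamming distance ≤ 1, the count being the number of
clusters. It is order-independent by construction (union–find over all
Hamming-1 pairs, found via a masked-position neighbour table rather than an
all-pairs scan).

## Image registration

Two transforms chain the spot grid onto the high-resolution image taken
before the run. (1) Grid → alignment image: the marker channels of each
capture area form a square fluorescent frame; the detector Otsu-thresholds
the channel, keeps the largest connected component, and takes the
minimum-area bounding rectangles of the component and of its enclosed hole,
averaging the two so the returned corners lie on the channel *center
lines* — the positions the grid model predicts. A manual-points TSV is
accepted wherever detection fails, replacing the interactive picking a
microscope operator would do. (2) Alignment → high-resolution image:
scale-invariant blob keypoints and descriptors on both nuclei channels,
nearest-neighbour matching with a 0.75 ratio test, and a robust affine by
random-sample consensus (3-point samples, 3 px inlier threshold, seeded)
refined by least squares on the inliers. Affine estimation from point pairs
solves the least-squares normal equations directly and is exact for three
non-collinear correspondences.

Spots landing outside the image are flagged, never dropped: a spot with
counts is data even when the microscope field missed it.

## Quality control

* **Tissue calling.** A spot is tissue iff its mean nuclei-stain intensity
  over the projected spot footprint reaches a threshold; Otsu's method on
  the per-spot intensity distribution is the default because the bimodality
  (glass vs nuclei) is exactly what Otsu assumes. A manual threshold is
  accepted.
* **Background gene filter.** Background spots receive reads only through
  ambient contamination, modelled as Poisson. For each gene, µ_b is its
  mean count over background spots and the keep threshold is
  t_g = µ_b + 2·√µ_b (mean plus two Poisson standard deviations). A gene is
  kept in a sample iff its mean over *tissue* spots exceeds t_g, and kept
  overall iff kept in at least one sample. Note the direction: the
  comparison is tissue-signal-above-background-derived-threshold; a gene
  whose tissue signal is statistically indistinguishable from its ambient
  level carries no spatial information and is removed. Under the Poisson
  model a pure-background gene passes with probability ≲ 2.5% (one-sided
  2σ), which the tests verify empirically. With no background spots the
  filter disables itself with a warning rather than guessing.
* **Stripe normalization.** Unequal flow across channels multiplies whole
  rows/columns of spots by a factor; scaling every spot to a common total
  (median by default, then optional log1p) removes it. The stripe metric is
  the coefficient of variation of per-row (and per-column) mean totals; it
  is exactly zero after total-count normalization by construction, which is
  why the acceptance report shows the raw and normalized CVs side by side
  rather than a ratio.
* **Saturation.** Reads (the retained read-record table, not an alignment
  file — keeping the analysis self-contained) are subsampled without
  replacement at each fraction with a seeded generator and the matrix is
  rebuilt; the curves of median UMIs/spot and genes/spot against fraction
  flatten as the library approaches saturation. The expected UMI recovery
  at fraction f with d reads per molecule is 1 − (1 − f)^d.
* **Pseudobulk.** Gene-wise sums over all spots, normalized to TPM when
  gene lengths are supplied and to counts-per-million otherwise (the output
  is labelled with the unit used), log1p-transformed, then Pearson
  correlation on shared genes.

## Wells and flow

Cross-contamination: each library (one per physical well) is decomposed by
the well its z-barcodes encode; row percentages sum to 100 and the
off-own-well share is the contamination estimate. Crosstalk-flagged reads
are counted before removal — they are the signal.

Flow: ordinary least squares of volumetric flow rate (µL/min) on channel
length (mm), with 95% confidence (mean) and prediction (new observation)
bands from the standard OLS theory; the prediction band always contains the
confidence band. The maximal operable length for a minimum flow q_min is
the point estimate (q_min − intercept)/slope, with a conservative variant
at the lower prediction bound. The idealized design model is the
first-order rectangular-duct approximation
Q = (w·h³·ΔP)/(12·µ·L)·(1 − 0.63·h/w), h ≤ w — an approximation that
captures the 1/L scaling but not measured chip-to-chip variation, and is
documented as such. Because the underlying measurement table is an
experimental artefact, the module treats measurements as input; the test
fixtures span the chip's length range 117.7–165.7 mm with four data points
per channel length (n = 152).

## The synthetic-data generator

The generator emulates the statistical structure each stage consumes, not
tissue biology: per-gene Poisson (optionally negative-binomial) counts on
tissue spots, ambient Poisson counts for planted contamination genes on all
spots, multiplicative row/column stripe factors, per-base substitution
errors, z-barcode well swaps at a configurable rate, duplicate reads per
molecule, and image pairs (nuclei as Gaussian blobs inside a central tissue
square, the marker frame along the alignment channels) rendered under known
affine transforms at 0.49 and 0.24 µm/px. Everything derives from one seed;
identical configs give byte-identical FASTQ and images.

Two deliberate generator properties:

* Within each (spot, gene) group, UMIs are rejection-sampled to pairwise
  Hamming distance ≥ 2 so the pipeline's Hamming-1 collapse can never merge
  two distinct true molecules — this is what makes the noise-free
  round-trip an *exact* matrix identity rather than an approximate one.
* Transcripts are random sequences (1 kb exonic, 300 nt intronic blocks)
  checked for 30-mer uniqueness across genes while being built, so
  prefix-based gene assignment is unambiguous by construction.

What the generator does **not** model: optics (point-spread functions,
autofluorescence), platform-specific error profiles (indels, quality decay
along the read), barcode synthesis errors, diffusion of barcodes beyond
the channel footprint, and biological covariance between genes. Passing
tests therefore demonstrate algorithmic correctness under the stated
statistical assumptions, not performance on real tissue.

## Problem sizes and defaults

Defaults that the method itself fixes are used verbatim: 38 channels,
50 µm channels at 100 µm pitch, 3 × 3 capture areas, outermost channels as
alignment marker, 8 nt barcodes, four z-barcodes per well at pairwise
Hamming ≥ 3 (the well sets the primer-mix design produces), 10 nt UMI,
0.49 / 0.24 µm/px imaging, max one barcode mismatch. Where the method fixes
no value we chose once: a 100-gene toy transcriptome at ~2 counts per gene
per tissue spot (real tissue has more genes at similar per-gene counts; the
pipeline is linear in both), 10 reads per molecule (a duplicate-heavy,
near-saturated library), 1% as a typical substitution-error rate in
error-model tests, and a central square covering ~50–60% of the capture
area as the tissue region.

Tests and the acceptance script run the full algorithm on scaled-down
chips — 8–12 channels at 20 µm/40 µm geometry, one or two capture areas,
~10⁵ reads, ~650–1900 px images — sizes chosen so the whole suite
exercises every code path in about a minute while keeping every statistical
check well-powered (binomial CIs at n = 10⁵, 20-seed decision accuracy,
100-replicate CI coverage).

## Known limitations

* The toy gene assigner requires exact 30-mer prefix matches; it is a
  stand-in interface for an aligner, not an aligner.
* Marker-frame detection assumes one dominant frame per image; multi-area
  images must be cropped per capture area first (the CLI registers one
  well at a time).
* The conservative operable-length bound is found by scanning the
  prediction band on a fixed grid (0.5 mm resolution at default spans), not
  by root-finding.
* `HammingMatcher` precomputes the variant table only for max_hamming ≤ 1;
  larger radii fall back to a linear scan per read.
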