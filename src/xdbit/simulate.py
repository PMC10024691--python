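"""Synthetic-data generator for every pipeline input.

Generates barcode legends, ground-truth count matrices, paired FASTQ
reads, fluorescence images and the true image transforms, with the
statistical structure the analysis stages assume:

* tissue spots draw per-gene counts from region means (Poisson by
  default, negative binomial optionally), background spots from an
  ambient Poisson rate; stripe factors multiply row/column means to mimic
  unequal channel flow;
* reads carry configurable per-base substitution errors and a
  well-contamination process that swaps z-barcodes between wells;
* images contain nuclei as Gaussian blobs inside the tissue region and
  the alignment-mark frame along the outermost channels, rendered at the
  alignment (0.49 µm/px) and high (0.24 µm/px) resolutions under known
  affine transforms.

Everything is driven by one seed: identical configs give byte-identical
FASTQ files and images.  Truth tables record every molecule and read, so
pipeline output can be compared against ground truth exactly.

One generator property matters for exact round-trips: within each
(spot, gene) group, UMIs are drawn with pairwise Hamming distance >= 2,
so the Hamming-1 UMI collapse of the pipeline can never merge two
distinct true molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chip_geometry import ChipLayout, SpotGrid, build_spot_grid
from .demux import (
    BarcodeLegend,
    CountMatrix,
    ReadLayout,
    ToyReference,
    default_read_layout,
    hamming,
)
from .registration import AffineTransform2D, ImagePlane

__all__ = [
    "SimulationConfig",
    "RenderedScene",
    "make_legend",
    "make_reference",
    "simulate_truth_counts",
    "simulate_reads",
    "render_images",
    "simulate_inputs",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the outputs.

    Defaults model the real chip: a 38-channel 3x3-area layout, 8 nt
    barcodes at pairwise Hamming distance >= 3, four z-barcodes per well,
    a 10 nt UMI, and imaging at 0.49 / 0.24 µm per pixel.  The toy
    transcriptome (100 genes of 1 kb) and the per-spot expression level
    are scaled down from real tissue so that simulated libraries stay
    small; the statistical structure, not the magnitude, is what the
    pipeline consumes.
    """

    seed: int = 0
    layout: ChipLayout = field(default_factory=ChipLayout)
    umi_length: int = 10
    barcode_length: int = 8
    linker_length: int = 30
    barcodes_per_well: int = 4
    min_barcode_hamming: int = 3
    # expression model
    n_genes: int = 100
    n_contamination_genes: int = 0  # ambient-only genes, Poisson everywhere
    expression_model: str = "poisson"  # or "nb"
    mean_expression_per_gene: float = 2.0
    nb_dispersion: float = 0.5
    lambda_bg: float = 0.0  # ambient rate of contamination genes
    tissue_fraction: float = 0.5  # side fraction of the central tissue square
    stripe_row_factors: np.ndarray | None = None
    stripe_col_factors: np.ndarray | None = None
    # read simulation
    reads_per_umi: int = 10
    read1_length: int = 50
    sequencing_error_rate: float = 0.0
    well_contamination_rate: float = 0.0
    intronic_read_fraction: float = 0.1
    gene_length: int = 1000
    intron_length: int = 300
    # imaging
    nuclei_per_area: int = 250
    nucleus_sigma_um: float = 2.0
    image_noise_sigma: float = 0.01
    alignment_pixel_size_um: float = 0.49
    hires_pixel_size_um: float = 0.24
    alignment_rotation_deg: float = 0.0
    hires_rotation_deg: float = 5.0
    image_margin_um: float = 50.0


# ---------------------------------------------------------------------------
# legends and reference
# ---------------------------------------------------------------------------

def _sample_barcode_set(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_hamming: int,
    max_attempts: int = 200_000,
) -> list[str]:
    """Rejection-sample ``n`` barcodes with pairwise Hamming >= min_hamming."""
    if min_hamming > length:
        raise ValueError("min_hamming cannot exceed the barcode length")
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"Hamming >= {min_hamming}"
            )
        cand = "".join(rng.choice(_BASES, size=length))
        if all(hamming(cand, a) >= min_hamming for a in accepted):
            accepted.append(cand)
    return accepted


def make_legend(
    seed: int,
    n_x: int,
    n_y: int,
    wells: list[str],
    barcodes_per_well: int = 4,
    min_hamming: int = 3,
    length: int = 8,
    x_indices: list[int] | None = None,
    y_indices: list[int] | None = None,
) -> BarcodeLegend:
    """Random barcode legend with guaranteed within-axis separation.

    ``x_indices`` / ``y_indices`` map the sampled barcodes onto specific
    channel indices (e.g. the barcoded channels of a layout whose
    outermost channels carry alignment marker); default 0..n-1.
    """
    rng = np.random.default_rng(seed)
    xs = _sample_barcode_set(rng, n_x, length, min_hamming)
    ys = _sample_barcode_set(rng, n_y, length, min_hamming)
    zs = _sample_barcode_set(rng, len(wells) * barcodes_per_well, length, min_hamming)
    if x_indices is None:
        x_indices = list(range(n_x))
    if y_indices is None:
        y_indices = list(range(n_y))
    if len(x_indices) != n_x or len(y_indices) != n_y:
        raise ValueError("index lists must match the barcode counts")
    z_map = {
        zs[w * barcodes_per_well + k]: well
        for w, well in enumerate(wells)
        for k in range(barcodes_per_well)
    }
    return BarcodeLegend(
        x=dict(zip(xs, x_indices)),
        y=dict(zip(ys, y_indices)),
        z=z_map,
    )


def make_reference(config: SimulationConfig, rng: np.random.Generator) -> ToyReference:
    """Random toy transcriptome: one exonic (and one intronic) record per gene.

    Sequences are random, so distinct genes share a 30-mer only with
    negligible probability; uniqueness is verified while building the
    prefix index and violating genes are resampled.
    """
    min_prefix = 30
    names = [f"g{i:04d}" for i in range(config.n_genes + config.n_contamination_genes)]
    records: list[tuple[str, str, str, str]] = []
    seen: set[str] = set()

    def fresh_seq(length: int) -> str:
        for _ in range(50):
            seq = "".join(rng.choice(_BASES, size=length))
            kmers = {seq[i : i + min_prefix] for i in range(length - min_prefix + 1)}
            if not (kmers & seen):
                seen.update(kmers)
                return seq
        raise RuntimeError("could not sample a collision-free transcript")

    for name in names:
        records.append((name, "tx1", "exonic", fresh_seq(config.gene_length)))
        if config.intronic_read_fraction > 0:
            records.append((name, "int1", "intronic", fresh_seq(config.intron_length)))
    return ToyReference(records, min_prefix=min_prefix)


# ---------------------------------------------------------------------------
# truth counts
# ---------------------------------------------------------------------------

def _tissue_mask_for_grid(grid: SpotGrid, tissue_fraction: float) -> np.ndarray:
    """Tissue truth labels: a centered square region per capture area."""
    layout = grid.layout
    span = layout.area_span_um
    half_tissue = tissue_fraction * span / 2.0
    mask = []
    for s in grid.spots:
        ox, oy = layout.section_origins[s.well_id]
        cx, cy = ox + span / 2.0, oy + span / 2.0
        x, y = s.center_um
        mask.append(abs(x - cx) <= half_tissue and abs(y - cy) <= half_tissue)
    return np.asarray(mask)


def simulate_truth_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Ground-truth spot x gene counts with per-spot truth labels.

    Tissue spots draw each real gene from its mean (scaled by the spot's
    stripe factors); background spots draw real genes at zero.  Planted
    contamination genes draw from ``lambda_bg`` on every spot, tissue and
    background alike, mimicking ambient material.  Only barcoded spots
    (both channels carrying spatial barcodes) are simulated.

    Returns the CountMatrix (rows = every barcoded spot, including
    all-zero ones) and a truth table with is_tissue and gene class labels
    stored in ``.attrs['gene_class']``.
    """
    rng = np.random.default_rng(config.seed)
    grid = build_spot_grid(config.layout)
    barcoded = [s for s in grid.spots if s.is_barcoded]
    tissue = _tissue_mask_for_grid(
        SpotGrid(config.layout, tuple(barcoded)), config.tissue_fraction
    )
    n_real, n_cont = config.n_genes, config.n_contamination_genes
    genes = [f"g{i:04d}" for i in range(n_real + n_cont)]
    gene_class = pd.Series(
        ["real"] * n_real + ["contamination"] * n_cont, index=genes
    )
    gene_means = np.full(n_real, config.mean_expression_per_gene)

    # per-spot stripe factor = row factor * column factor
    def factor(vals: np.ndarray | None, idx: int) -> float:
        return 1.0 if vals is None else float(np.asarray(vals)[idx])

    rows = np.zeros((len(barcoded), n_real + n_cont), dtype=int)
    for i, s in enumerate(barcoded):
        f = factor(config.stripe_row_factors, s.y_idx) * factor(
            config.stripe_col_factors, s.x_idx
        )
        if tissue[i]:
            lam = gene_means * f
            if config.expression_model == "poisson":
                rows[i, :n_real] = rng.poisson(lam)
            elif config.expression_model == "nb":
                r = 1.0 / config.nb_dispersion
                p = r / (r + lam)
                rows[i, :n_real] = rng.negative_binomial(r, p)
            else:
                raise ValueError(f"unknown expression model {config.expression_model!r}")
        if n_cont and config.lambda_bg > 0:
            rows[i, n_real:] = rng.poisson(config.lambda_bg * f, size=n_cont)
    spot_ids = [f"{s.well_id}_x{s.x_idx:02d}_y{s.y_idx:02d}" for s in barcoded]
    counts = pd.DataFrame(rows, index=pd.Index(spot_ids, name="spot_id"), columns=genes)
    spots = pd.DataFrame(
        {
            "well_id": [s.well_id for s in barcoded],
            "x_idx": [s.x_idx for s in barcoded],
            "y_idx": [s.y_idx for s in barcoded],
            "x_um": [s.center_um[0] for s in barcoded],
            "y_um": [s.center_um[1] for s in barcoded],
            "is_tissue": tissue,
        },
        index=counts.index,
    )
    spots["total_umis"] = counts.sum(axis=1)
    spots["n_genes"] = (counts > 0).sum(axis=1)
    matrix = CountMatrix(counts, spots)
    truth = spots.copy()
    truth.attrs["gene_class"] = gene_class
    return matrix, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _sample_umis(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 2
) -> list[str]:
    """UMIs for one (spot, gene) group, pairwise Hamming >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(_BASES, size=length))
        if all(hamming(cand, u) >= min_dist for u in out):
            out.append(cand)
    return out


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_reads(
    truth: CountMatrix,
    config: SimulationConfig,
    legend: BarcodeLegend,
    reference: ToyReference,
    read_layout: ReadLayout | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Paired reads for every molecule of a truth matrix, plus truth table.

    Each count in the truth matrix becomes one molecule; each molecule is
    sequenced ``reads_per_umi`` times.  Read 2 is assembled from the
    legend sequences of the molecule's spot, a linker, and the molecule's
    UMI; read 1 is a substring of the assigned gene's transcript (exonic,
    or intronic for a configurable fraction of molecules).  Substitution
    errors and z-barcode well swaps are applied at the configured rates
    and recorded per read in the truth table.

    Returns (read1 list, read2 list, truth_reads) where the lists hold
    (read_id, sequence) pairs in deterministic order.
    """
    rng = np.random.default_rng(config.seed + 1)
    if read_layout is None:
        read_layout = default_read_layout(
            umi_length=config.umi_length,
            barcode_length=config.barcode_length,
            linker_length=config.linker_length,
        )
    linker = "".join(rng.choice(_BASES, size=config.linker_length))
    x_by_idx = {i: s for s, i in legend.x.items()}
    y_by_idx = {i: s for s, i in legend.y.items()}
    z_by_well: dict[str, list[str]] = {}
    for seq, well in legend.z.items():
        z_by_well.setdefault(well, []).append(seq)
    wells = list(z_by_well)
    tx_by_gene: dict[str, dict[str, list[str]]] = {}
    for gene, _tx, region, seq in reference.records:
        tx_by_gene.setdefault(gene, {}).setdefault(region, []).append(seq)

    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    rows = []
    counts = truth.counts
    meta = truth.spots
    read_no = 0
    for spot_id in counts.index:
        spot = meta.loc[spot_id]
        gene_counts = counts.loc[spot_id]
        for gene in counts.columns[gene_counts.to_numpy() > 0]:
            n_mol = int(gene_counts[gene])
            umis = _sample_umis(rng, n_mol, config.umi_length)
            for umi in umis:
                region = (
                    "intronic"
                    if (
                        config.intronic_read_fraction > 0
                        and "intronic" in tx_by_gene[gene]
                        and rng.random() < config.intronic_read_fraction
                    )
                    else "exonic"
                )
                seq_pool = tx_by_gene[gene][region]
                tx = seq_pool[rng.integers(len(seq_pool))]
                start = int(rng.integers(len(tx) - config.read1_length + 1))
                cdna = tx[start : start + config.read1_length]
                for _dup in range(config.reads_per_umi):
                    well = spot["well_id"]
                    status = "valid"
                    if (
                        config.well_contamination_rate > 0
                        and len(wells) > 1
                        and rng.random() < config.well_contamination_rate
                    ):
                        others = [w for w in wells if w != well]
                        well = others[rng.integers(len(others))]
                        status = "crosstalk"
                    z_seq = z_by_well[well][rng.integers(len(z_by_well[well]))]
                    parts = {
                        "umi": umi,
                        "x_barcode": x_by_idx[int(spot["x_idx"])],
                        "y_barcode": y_by_idx[int(spot["y_idx"])],
                        "z_barcode": z_seq,
                    }
                    read2 = "".join(
                        parts.get(seg.role, linker[: seg.length])
                        for seg in sorted(read_layout.segments, key=lambda s: s.start)
                    )
                    read2 = _with_errors(rng, read2, config.sequencing_error_rate)
                    read1 = _with_errors(rng, cdna, config.sequencing_error_rate)
                    rid = f"read{read_no:08d}"
                    read_no += 1
                    r1.append((rid, read1))
                    r2.append((rid, read2))
                    rows.append(
                        (
                            rid, spot_id, spot["well_id"], int(spot["x_idx"]),
                            int(spot["y_idx"]), gene, umi, region, well, status,
                        )
                    )
    truth_reads = pd.DataFrame(
        rows,
        columns=[
            "read_id", "spot_id", "well_id", "x_idx", "y_idx", "gene", "umi",
            "region", "z_well", "status",
        ],
    )
    return r1, r2, truth_reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedScene:
    """Synthetic imaging output with its ground-truth transforms."""

    alignment_dapi: ImagePlane
    alignment_marker: ImagePlane
    hires_dapi: ImagePlane
    t_grid_to_alignment: AffineTransform2D
    t_alignment_to_hires: AffineTransform2D
    nuclei_um: np.ndarray

    @property
    def t_grid_to_hires(self) -> AffineTransform2D:
        return self.t_alignment_to_hires.compose(self.t_grid_to_alignment)


def _stamp_gaussians(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amplitudes: np.ndarray,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    r = max(int(np.ceil(4 * sigma_px)), 2)
    nrows, ncols = shape
    for (x, y), amp in zip(centers_px, amplitudes):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - r, 0), min(cx + r + 1, ncols)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, nrows)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
        img[y0:y1, x0:x1] += amp * g
    return img


def _draw_segment(
    img: np.ndarray, p0: np.ndarray, p1: np.ndarray, width_px: float
) -> None:
    """Additive rasterisation of a thick line segment."""
    nrows, ncols = img.shape
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(length), 2)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    half = max(int(round(width_px / 2)), 1)
    for x, y in pts:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, ncols)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, nrows)
        img[y0:y1, x0:x1] = 1.0


def _frame_corners_um(layout: ChipLayout, well_id: str) -> np.ndarray:
    lo, hi = min(layout.alignment_channels), max(layout.alignment_channels)
    ox, oy = layout.section_origins[well_id]
    half = layout.channel_width / 2.0
    c = lambda i: i * layout.pitch + half
    return np.array(
        [
            [ox + c(lo), oy + c(lo)],
            [ox + c(hi), oy + c(lo)],
            [ox + c(hi), oy + c(hi)],
            [ox + c(lo), oy + c(hi)],
        ]
    )


def render_images(
    config: SimulationConfig, wells: list[str] | None = None
) -> RenderedScene:
    """Render the alignment and high-resolution images of a (sub)scene.

    The scene covers the given wells (default: the first capture area).
    Nuclei are placed uniformly inside each well's tissue square; the
    alignment-mark frame runs along the center lines of the outermost
    alignment channels.  The alignment image is rendered at
    ``alignment_pixel_size_um`` under a rigid grid->image transform, the
    high-resolution image at ``hires_pixel_size_um`` under an additional
    rotation; both true transforms are returned.
    """
    rng = np.random.default_rng(config.seed + 2)
    layout = config.layout
    if wells is None:
        wells = [layout.well_ids[0]]
    span = layout.area_span_um

    # nuclei inside the tissue square of each rendered well
    nuclei = []
    for well in wells:
        ox, oy = layout.section_origins[well]
        c = np.array([ox + span / 2.0, oy + span / 2.0])
        half = config.tissue_fraction * span / 2.0
        pts = c + rng.uniform(-half, half, size=(config.nuclei_per_area, 2))
        nuclei.append(pts)
    nuclei_um = np.vstack(nuclei)

    # scene bounding box in µm
    mins = np.array([layout.section_origins[w] for w in wells]).min(axis=0)
    maxs = (
        np.array([layout.section_origins[w] for w in wells]).max(axis=0) + span
    )
    margin = config.image_margin_um

    def build_transform(pixel_size: float, rotation_deg: float) -> AffineTransform2D:
        t = AffineTransform2D.from_components(
            scale=1.0 / pixel_size, rotation_deg=rotation_deg
        )
        # translate so the rotated scene (with margin) lands in positive px
        corners = np.array(
            [
                [mins[0] - margin, mins[1] - margin],
                [maxs[0] + margin, mins[1] - margin],
                [maxs[0] + margin, maxs[1] + margin],
                [mins[0] - margin, maxs[1] + margin],
            ]
        )
        moved = t.apply(corners)
        shift = -moved.min(axis=0)
        m = t.matrix.copy()
        m[:, 2] += shift
        return AffineTransform2D(m)

    def image_shape(t: AffineTransform2D) -> tuple[int, int]:
        corners = np.array(
            [
                [mins[0] - margin, mins[1] - margin],
                [maxs[0] + margin, mins[1] - margin],
                [maxs[0] + margin, maxs[1] + margin],
                [mins[0] - margin, maxs[1] + margin],
            ]
        )
        moved = t.apply(corners)
        return (
            int(np.ceil(moved[:, 1].max())) + 1,
            int(np.ceil(moved[:, 0].max())) + 1,
        )

    def render(t: AffineTransform2D, pixel_size: float):
        shape = image_shape(t)
        sigma_px = config.nucleus_sigma_um / pixel_size
        amps = 0.5 + 0.5 * np.random.default_rng(config.seed + 3).random(
            len(nuclei_um)
        )
        dapi = _stamp_gaussians(shape, t.apply(nuclei_um), sigma_px, amps)
        marker = np.zeros(shape, dtype=float)
        width_px = layout.channel_width / pixel_size
        for well in wells:
            corners = t.apply(_frame_corners_um(layout, well))
            for a, b in zip(corners, np.roll(corners, -1, axis=0)):
                _draw_segment(marker, a, b, width_px)
        if config.image_noise_sigma > 0:
            noise_rng = np.random.default_rng(config.seed + 4)
            dapi = dapi + noise_rng.normal(0, config.image_noise_sigma, shape)
            marker = marker + noise_rng.normal(0, config.image_noise_sigma, shape)
        return np.clip(dapi, 0, None), np.clip(marker, 0, None)

    t_align = build_transform(
        config.alignment_pixel_size_um, config.alignment_rotation_deg
    )
    t_hires = build_transform(config.hires_pixel_size_um, config.hires_rotation_deg)
    dapi_a, marker_a = render(t_align, config.alignment_pixel_size_um)
    dapi_h, _ = render(t_hires, config.hires_pixel_size_um)
    return RenderedScene(
        alignment_dapi=ImagePlane(dapi_a, config.alignment_pixel_size_um, "nuclei"),
        alignment_marker=ImagePlane(
            marker_a, config.alignment_pixel_size_um, "marker"
        ),
        hires_dapi=ImagePlane(dapi_h, config.hires_pixel_size_um, "nuclei"),
        t_grid_to_alignment=t_align,
        t_alignment_to_hires=t_hires.compose(t_align.invert()),
        nuclei_um=nuclei_um,
    )


# ---------------------------------------------------------------------------
# one-call input generation
# ---------------------------------------------------------------------------

def simulate_inputs(config: SimulationConfig, out_dir=None):
    """Generate legend, reference, truth counts, reads and images together.

    Returns a dict with keys legend, reference, truth, truth_spots, r1,
    r2, truth_reads, scene, read_layout.  With ``out_dir`` the file-based
    artefacts (FASTQ, legend CSV, reference FASTA, layout grid TSV, truth
    tables, images, true transforms) are also written to disk.
    """
    layout = config.layout
    barcoded = sorted(set(range(layout.n_channels)) - layout.alignment_channels)
    legend = make_legend(
        config.seed,
        n_x=len(barcoded),
        n_y=len(barcoded),
        wells=layout.well_ids,
        barcodes_per_well=config.barcodes_per_well,
        min_hamming=config.min_barcode_hamming,
        length=config.barcode_length,
        x_indices=barcoded,
        y_indices=barcoded,
    )
    rng = np.random.default_rng(config.seed + 5)
    reference = make_reference(config, rng)
    truth, truth_spots = simulate_truth_counts(config)
    read_layout = default_read_layout(
        umi_length=config.umi_length,
        barcode_length=config.barcode_length,
        linker_length=config.linker_length,
    )
    r1, r2, truth_reads = simulate_reads(truth, config, legend, reference, read_layout)
    scene = render_images(config)
    result = {
        "legend": legend,
        "reference": reference,
        "truth": truth,
        "truth_spots": truth_spots,
        "r1": r1,
        "r2": r2,
        "truth_reads": truth_reads,
        "scene": scene,
        "read_layout": read_layout,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(r1, out / "reads_R1.fastq.gz")
        write_fastq(r2, out / "reads_R2.fastq.gz")
        legend.to_csv(out / "legend.csv")
        reference.to_fasta(out / "reference.fasta")
        build_spot_grid(layout).to_tsv(out / "grid.tsv")
        truth.to_mtx(out / "truth_counts")
        truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        scene.t_grid_to_alignment.to_json(out / "t_grid_to_alignment.json")
        scene.t_alignment_to_hires.to_json(out / "t_alignment_to_hires.json")
        try:
            import tifffile

            tifffile.imwrite(
                out / "alignment_dapi.tif",
                scene.alignment_dapi.data.astype(np.float32),
            )
            tifffile.imwrite(
                out / "alignment_marker.tif",
                scene.alignment_marker.data.astype(np.float32),
            )
            tifffile.imwrite(
                out / "hires_dapi.tif", scene.hires_dapi.data.astype(np.float32)
            )
        except ImportError:  # pragma: no cover
            pass
    return result
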