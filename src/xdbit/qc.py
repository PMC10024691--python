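"""Preprocessing and quality-control computations.

After demultiplexing, spots fall into two classes: tissue spots covered by
the section and background spots on bare glass.  Background spots receive
reads only through ambient contamination, which is modelled as Poisson.
This module implements the preprocessing steps that exploit that split:

* tissue/background calling from the mean nuclei-stain intensity per spot,
* the Poisson background gene filter: a gene with mean background count
  mu_b is kept in a sample only if its mean over tissue spots exceeds
  t_g = mu_b + 2 * sqrt(mu_b), i.e. two standard deviations above the
  background mean under the Poisson assumption,
* per-spot total-count normalization, which removes the stripe artifacts
  caused by unequal flow in individual channels,
* a stripe metric (coefficient of variation of row/column totals),
* sequencing-saturation analysis by seeded read subsampling,
* marker-gene presence per organ set and pseudobulk correlation against
  bulk RNA-seq profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .demux import CountMatrix, digital_expression

__all__ = [
    "BackgroundModel",
    "SaturationCurve",
    "spot_image_means",
    "flag_tissue_spots",
    "background_gene_filter",
    "normalize_spots",
    "stripe_metric",
    "subsample_saturation",
    "marker_presence",
    "pseudobulk_correlate",
]


# ---------------------------------------------------------------------------
# tissue calling
# ---------------------------------------------------------------------------

def spot_image_means(
    image: np.ndarray, spot_px: pd.DataFrame, half_width_px: float
) -> pd.Series:
    """Mean image intensity inside each spot's square footprint.

    ``spot_px`` needs x_px / y_px columns (spot centers in pixel space);
    the footprint is the axis-aligned square of half-side
    ``half_width_px`` clipped to the image.
    """
    img = np.asarray(image, float)
    nrows, ncols = img.shape
    means = []
    for row in spot_px.itertuples():
        x0 = int(np.clip(round(row.x_px - half_width_px), 0, ncols))
        x1 = int(np.clip(round(row.x_px + half_width_px) + 1, 0, ncols))
        y0 = int(np.clip(round(row.y_px - half_width_px), 0, nrows))
        y1 = int(np.clip(round(row.y_px + half_width_px) + 1, 0, nrows))
        patch = img[y0:y1, x0:x1]
        means.append(float(patch.mean()) if patch.size else np.nan)
    return pd.Series(means, index=spot_px.index, name="dapi_mean")


def flag_tissue_spots(
    matrix: CountMatrix,
    dapi_spot_means: pd.Series,
    threshold: float | None = None,
) -> pd.Series:
    """Boolean tissue mask per spot from mean nuclei-stain intensity.

    A spot is tissue iff its mean intensity is >= the threshold; with
    ``threshold=None`` the threshold is chosen automatically by Otsu's
    method on the per-spot intensity distribution.  The mask is also
    written into ``matrix.spots['is_tissue']``.
    """
    means = dapi_spot_means.reindex(matrix.spots.index)
    if means.isna().any():
        raise ValueError("missing intensity for some spots")
    if threshold is None:
        vals = means.to_numpy(float)
        threshold = float(threshold_otsu(vals)) if len(np.unique(vals)) > 1 else 0.0
    mask = means >= threshold
    matrix.spots["is_tissue"] = mask
    matrix.spots["dapi_mean"] = means
    return mask


# ---------------------------------------------------------------------------
# background gene filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundModel:
    """Per-gene ambient background level and derived keep threshold."""

    mu_b: pd.Series  # mean count over background spots

    @property
    def t_g(self) -> pd.Series:
        """Threshold two Poisson standard deviations above the mean."""
        return self.mu_b + 2.0 * np.sqrt(self.mu_b)


def background_gene_filter(
    matrices: CountMatrix | Sequence[CountMatrix],
    background_masks: pd.Series | Sequence[pd.Series] | None = None,
) -> tuple[pd.Series, list[pd.Series], list[BackgroundModel]]:
    """Remove genes indistinguishable from ambient background.

    For each sample, every gene's background mean mu_b over background
    spots defines a threshold t_g = mu_b + 2*sqrt(mu_b); the gene is kept
    in that sample iff its mean over tissue spots exceeds t_g.  The
    combined mask keeps a gene if any sample keeps it.

    Masks default to each matrix's ``is_tissue`` column.  A sample with no
    background spots cannot be filtered: all its genes are kept and a
    warning is emitted.

    Returns
    -------
    (combined_keep, per_sample_keep, per_sample_models) indexed by gene.
    """
    import warnings

    if isinstance(matrices, CountMatrix):
        matrices = [matrices]
        if background_masks is not None and isinstance(background_masks, pd.Series):
            background_masks = [background_masks]
    per_sample: list[pd.Series] = []
    models: list[BackgroundModel] = []
    for i, mat in enumerate(matrices):
        if background_masks is not None:
            tissue = ~background_masks[i].reindex(mat.counts.index).astype(bool)
        else:
            tissue = mat.spots["is_tissue"].astype(bool)
        bg = ~tissue
        genes = mat.counts.columns
        if bg.sum() == 0:
            warnings.warn(
                "no background spots in sample; background gene filter disabled",
                stacklevel=2,
            )
            per_sample.append(pd.Series(True, index=genes))
            models.append(BackgroundModel(pd.Series(0.0, index=genes)))
            continue
        mu_b = mat.counts.loc[bg.to_numpy()].mean(axis=0)
        model = BackgroundModel(mu_b)
        tissue_mean = (
            mat.counts.loc[tissue.to_numpy()].mean(axis=0)
            if tissue.sum()
            else pd.Series(0.0, index=genes)
        )
        per_sample.append(tissue_mean > model.t_g)
        models.append(model)
    all_genes = per_sample[0].index
    for ps in per_sample[1:]:
        all_genes = all_genes.union(ps.index)
    combined = pd.Series(False, index=all_genes)
    for ps in per_sample:
        combined |= ps.reindex(all_genes, fill_value=False)
    return combined, per_sample, models


# ---------------------------------------------------------------------------
# normalization and stripe metric
# ---------------------------------------------------------------------------

def normalize_spots(
    matrix: CountMatrix,
    target_sum: float | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Scale every spot to a common total count; optional log(1+x).

    Equal per-spot totals remove the channel-wise stripe bias.  The
    default target is the median of the observed spot totals.  Spots with
    zero total cannot be scaled and are dropped (with a log entry on the
    returned frame's attrs).
    """
    totals = matrix.counts.sum(axis=1).astype(float)
    if (totals == 0).all():
        raise ValueError("all-zero count matrix cannot be normalized")
    nz = totals > 0
    dropped = list(matrix.counts.index[~nz])
    counts = matrix.counts.loc[nz.to_numpy()].astype(float)
    totals = totals[nz]
    if target_sum is None:
        target_sum = float(totals.median())
    norm = counts.mul(target_sum / totals, axis=0)
    if log_transform:
        norm = np.log1p(norm)
    norm.attrs["dropped_zero_total_spots"] = dropped
    norm.attrs["target_sum"] = target_sum
    norm.attrs["log_transformed"] = log_transform
    return norm


def _cv(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    if len(values) < 2:
        return 0.0
    mean = values.mean()
    return float(values.std(ddof=0) / mean) if mean > 0 else 0.0


def stripe_metric(
    counts: pd.DataFrame, spots: pd.DataFrame
) -> tuple[float, float]:
    """Coefficient of variation of per-row and per-column mean totals.

    Rows are grouped by y_idx, columns by x_idx (over all wells).  A grid
    with a single row or column has no defined CV and reports 0.
    """
    totals = counts.sum(axis=1)
    meta = spots.loc[counts.index]
    row_means = totals.groupby(meta["y_idx"]).mean()
    col_means = totals.groupby(meta["x_idx"]).mean()
    return _cv(row_means.to_numpy()), _cv(col_means.to_numpy())


# ---------------------------------------------------------------------------
# saturation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationCurve:
    """Median per-spot complexity as a function of read subsampling."""

    fractions: tuple[float, ...]
    median_umis_per_spot: tuple[float, ...]
    median_genes_per_spot: tuple[float, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "median_umis_per_spot": self.median_umis_per_spot,
                "median_genes_per_spot": self.median_genes_per_spot,
            }
        )


def subsample_saturation(
    read_records: pd.DataFrame,
    fractions: Sequence[float],
    seed: int = 0,
    include_intronic: bool = True,
) -> SaturationCurve:
    """Rebuild the count matrix from random read subsets.

    For each fraction f the retained read-record table (one row per valid,
    gene-assigned read) is sampled without replacement with a seeded
    generator, the spot x gene matrix is rebuilt by UMI collapse, and the
    median UMIs/spot and genes/spot are recorded.  Saturated libraries
    show flat curves; unsaturated ones keep rising towards f = 1.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
    usable = read_records.dropna(subset=["gene"])
    rng = np.random.default_rng(seed)
    med_u, med_g = [], []
    for f in fractions:
        if f == 1.0:
            sub = usable
        else:
            n = int(round(f * len(usable)))
            idx = rng.choice(len(usable), size=n, replace=False)
            sub = usable.iloc[np.sort(idx)]
        if sub.empty:
            med_u.append(0.0)
            med_g.append(0.0)
            continue
        mat = digital_expression(sub, include_intronic=include_intronic)
        med_u.append(float(mat.spots["total_umis"].median()))
        med_g.append(float(mat.spots["n_genes"].median()))
    return SaturationCurve(
        fractions=tuple(fractions),
        median_umis_per_spot=tuple(med_u),
        median_genes_per_spot=tuple(med_g),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# marker presence and pseudobulk correlation
# ---------------------------------------------------------------------------

def marker_presence(
    matrix: CountMatrix | pd.DataFrame,
    marker_sets: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Fraction of each marker set detected (nonzero counts) in the data.

    Gene identifiers are compared case-insensitively.  Used to check that
    organ-specific signal survives, and cross-organ spillover does not
    survive, the background gene filter.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    detected = {
        str(g).lower() for g in counts.columns[(counts.sum(axis=0) > 0).to_numpy()]
    }
    out = {}
    for name, genes in marker_sets.items():
        if len(genes) == 0:
            raise ValueError(f"marker set {name!r} is empty")
        out[name] = sum(str(g).lower() in detected for g in genes) / len(genes)
    return pd.Series(out, name="marker_presence")


def _to_expression_profile(
    values: pd.Series, gene_lengths: pd.Series | None
) -> pd.Series:
    """TPM when gene lengths are available, else counts-per-million."""
    v = values.astype(float)
    if gene_lengths is not None:
        rate = v / gene_lengths.reindex(v.index).astype(float)
        profile = rate / rate.sum() * 1e6
        profile.attrs["unit"] = "TPM"
    else:
        profile = v / v.sum() * 1e6
        profile.attrs["unit"] = "CPM"
    return np.log1p(profile)


def pseudobulk_correlate(
    matrix: CountMatrix,
    bulk_table: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
) -> pd.Series:
    """Pearson correlation of the spatial pseudobulk with bulk profiles.

    The pseudobulk is the gene-wise sum over all spots.  Both sides are
    normalised to transcripts-per-million (or counts-per-million when no
    gene lengths are supplied, labelled accordingly) and log(1+x)
    transformed before correlating on the shared genes.
    """
    pseudo = matrix.pseudobulk()
    pseudo.index = pseudo.index.str.lower()
    bulk = bulk_table.copy()
    bulk.index = bulk.index.astype(str).str.lower()
    if gene_lengths is not None:
        gene_lengths = gene_lengths.copy()
        gene_lengths.index = gene_lengths.index.astype(str).str.lower()
    shared = pseudo.index.intersection(bulk.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between pseudobulk and bulk")
    p = _to_expression_profile(pseudo.loc[shared], gene_lengths)
    out = {}
    for col in bulk.columns:
        b = _to_expression_profile(bulk.loc[shared, col], gene_lengths)
        out[col] = float(np.corrcoef(p.to_numpy(), b.to_numpy())[0, 1])
    return pd.Series(out, name="pearson_r")
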