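"""Tissue calling, background gene filter, normalization, saturation, pseudobulk."""

import numpy as np
import pandas as pd
import pytest

from xdbit.demux import CountMatrix
from xdbit.qc import (
    BackgroundModel,
    background_gene_filter,
    flag_tissue_spots,
    marker_presence,
    normalize_spots,
    pseudobulk_correlate,
    spot_image_means,
    stripe_metric,
    subsample_saturation,
)


def make_matrix(counts: np.ndarray, x_idx=None, y_idx=None) -> CountMatrix:
    n, g = counts.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="spot_id")
    spots = pd.DataFrame(
        {
            "well_id": "A1",
            "x_idx": x_idx if x_idx is not None else np.arange(n),
            "y_idx": y_idx if y_idx is not None else np.zeros(n, int),
        },
        index=idx,
    )
    return CountMatrix(
        pd.DataFrame(counts.astype(int), index=idx, columns=[f"g{j}" for j in range(g)]),
        spots,
    )


class TestTissueCalling:
    def test_fixed_threshold(self):
        mat = make_matrix(np.ones((4, 2)))
        means = pd.Series([0.0, 0.0, 100.0, 100.0], index=mat.counts.index)
        mask = flag_tissue_spots(mat, means, threshold=50.0)
        assert list(mask) == [False, False, True, True]

    def test_zero_threshold_keeps_all(self):
        mat = make_matrix(np.ones((3, 2)))
        means = pd.Series([0.0, 5.0, 9.0], index=mat.counts.index)
        assert flag_tissue_spots(mat, means, threshold=0.0).all()

    def test_otsu_auto_threshold_recovers_truth(self):
        """Bimodal intensities (glass vs nuclei) are split >= 95% correctly."""
        rng = np.random.default_rng(0)
        n = 200
        truth = np.arange(n) < n // 2
        means = np.where(truth, rng.normal(120, 10, n), rng.normal(10, 5, n))
        mat = make_matrix(np.ones((n, 2)))
        mask = flag_tissue_spots(mat, pd.Series(means, index=mat.counts.index))
        assert (mask.to_numpy() == truth).mean() >= 0.95

    def test_missing_intensity_rejected(self):
        mat = make_matrix(np.ones((3, 2)))
        means = pd.Series([1.0, 2.0], index=mat.counts.index[:2])
        with pytest.raises(ValueError):
            flag_tissue_spots(mat, means, threshold=0.5)

    def test_spot_image_means_reads_patches(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 50.0
        spot_px = pd.DataFrame(
            {"x_px": [4.0, 15.0], "y_px": [10.0, 10.0]}, index=["a", "b"]
        )
        means = spot_image_means(img, spot_px, half_width_px=2)
        assert means["a"] == 0.0 and means["b"] == 50.0


class TestBackgroundGeneFilter:
    def test_threshold_formula(self):
        """mu_b = 4 gives t_g = 8: tissue mean 9 is kept, 7 removed;
        mu_b = 0 gives t_g = 0 and any positive tissue signal survives."""
        model = BackgroundModel(pd.Series({"g_keep": 4.0, "g_drop": 4.0, "g_z": 0.0}))
        assert model.t_g["g_keep"] == 8.0
        counts = np.zeros((4, 3), dtype=int)
        # 2 background spots, 2 tissue spots; per-gene tissue means 9, 7, 0.5
        counts[0:2, 0] = 4; counts[2:4, 0] = 9
        counts[0:2, 1] = 4; counts[2:4, 1] = 7
        counts[2, 2] = 1
        mat = make_matrix(counts)
        mat.spots["is_tissue"] = [False, False, True, True]
        keep, per_sample, models = background_gene_filter(mat)
        assert models[0].mu_b.tolist() == [4.0, 4.0, 0.0]
        assert keep.tolist() == [True, False, True]

    def test_threshold_monotone_in_background_mean(self):
        mu = pd.Series(np.linspace(0, 50, 101))
        t = BackgroundModel(mu).t_g
        assert (np.diff(t) > 0).all()

    def test_spot_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, size=(30, 8))
        mat = make_matrix(counts)
        mat.spots["is_tissue"] = rng.random(30) < 0.6
        keep, _, _ = background_gene_filter(mat)
        perm = rng.permutation(30)
        mat2 = CountMatrix(mat.counts.iloc[perm], mat.spots.iloc[perm])
        keep2, _, _ = background_gene_filter(mat2)
        assert keep.equals(keep2)

    def test_combined_keeps_gene_found_in_any_sample(self):
        counts_a = np.array([[0, 0], [10, 0]])
        counts_b = np.array([[0, 0], [0, 10]])
        mats = []
        for c in (counts_a, counts_b):
            m = make_matrix(c)
            m.spots["is_tissue"] = [False, True]
            mats.append(m)
        keep, per_sample, _ = background_gene_filter(mats)
        assert keep.tolist() == [True, True]
        assert per_sample[0].tolist() == [True, False]

    def test_no_background_spots_disables_filter(self):
        mat = make_matrix(np.ones((3, 2)))
        mat.spots["is_tissue"] = True
        with pytest.warns(UserWarning):
            keep, _, _ = background_gene_filter(mat)
        assert keep.all()

    def test_planted_genes_classified_correctly(self):
        """Background-only genes (ambient Poisson lambda=2 everywhere) are
        removed and 10x-enriched tissue genes kept, >= 99% each way."""
        correct_cont, correct_real, n_cont, n_real = 0, 0, 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_bg_spots, n_t_spots = 40, 60
            lam = 2.0
            cont = rng.poisson(lam, size=(n_bg_spots + n_t_spots, 25))
            real = np.vstack(
                [
                    rng.poisson(0.0, size=(n_bg_spots, 25)),
                    rng.poisson(10 * lam, size=(n_t_spots, 25)),
                ]
            )
            mat = make_matrix(np.hstack([real, cont]))
            mat.spots["is_tissue"] = np.arange(100) >= n_bg_spots
            keep, _, _ = background_gene_filter(mat)
            correct_real += keep[:25].sum(); n_real += 25
            correct_cont += (~keep[25:]).sum(); n_cont += 25
        assert correct_real / n_real >= 0.99
        assert correct_cont / n_cont >= 0.99

    def test_pure_background_false_keep_rate_within_poisson_bound(self):
        """A gene whose tissue and background signal are the same Poisson
        noise passes the 2-sigma threshold at most ~2.5% of the time."""
        rng = np.random.default_rng(7)
        n_genes = 10_000
        lam = 2.0
        n_bg, n_tis = 200, 200
        bg = rng.poisson(lam, size=(n_bg, n_genes))
        tis = rng.poisson(lam, size=(n_tis, n_genes))
        mu_b = bg.mean(axis=0)
        t_g = mu_b + 2 * np.sqrt(mu_b)
        false_keep = (tis.mean(axis=0) > t_g).mean()
        # one-sided 2-sigma bound plus binomial 99% CI head-room
        ci = 3 * np.sqrt(0.025 * 0.975 / n_genes)
        assert false_keep <= 0.025 + ci


class TestNormalization:
    def test_totals_equalized(self):
        mat = make_matrix(np.array([[50, 50], [150, 50]]))
        norm = normalize_spots(mat, target_sum=100.0)
        assert np.allclose(norm.sum(axis=1), 100.0)

    def test_no_log_keeps_rational_scaling(self):
        mat = make_matrix(np.array([[2, 2], [4, 4]]))
        norm = normalize_spots(mat, target_sum=4.0)
        assert np.allclose(norm.to_numpy(), [[2.0, 2.0], [2.0, 2.0]])

    def test_log_preserves_zeros(self):
        mat = make_matrix(np.array([[5, 0], [3, 1]]))
        norm = normalize_spots(mat, log_transform=True)
        assert norm.iloc[0, 1] == 0.0

    def test_zero_total_spots_dropped_and_logged(self):
        mat = make_matrix(np.array([[5, 5], [0, 0]]))
        norm = normalize_spots(mat)
        assert len(norm) == 1
        assert norm.attrs["dropped_zero_total_spots"] == ["s1"]

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            normalize_spots(make_matrix(np.zeros((2, 2))))


class TestStripeMetric:
    def grid_matrix(self, values):
        """values: (n_rows, n_cols) spot totals laid on a grid, 1 gene."""
        arr = np.asarray(values)
        n_rows, n_cols = arr.shape
        y, x = np.divmod(np.arange(n_rows * n_cols), n_cols)
        return make_matrix(arr.reshape(-1, 1), x_idx=x, y_idx=y)

    def test_uniform_grid_has_zero_cv(self):
        mat = self.grid_matrix(np.full((4, 4), 7))
        assert stripe_metric(mat.counts, mat.spots) == (0.0, 0.0)

    def test_doubled_row_closed_form(self):
        """Rows {2u, u} give CV = (u/2)/(3u/2) = 1/3 exactly."""
        mat = self.grid_matrix(np.array([[2, 2], [1, 1]]))
        row_cv, col_cv = stripe_metric(mat.counts, mat.spots)
        assert row_cv == pytest.approx(1.0 / 3.0)
        assert col_cv == 0.0

    def test_single_row_reports_zero(self):
        mat = self.grid_matrix(np.array([[1, 5, 9]]))
        row_cv, _ = stripe_metric(mat.counts, mat.spots)
        assert row_cv == 0.0

    def test_normalization_reduces_injected_stripes(self):
        """Multiplicative row factors 0.5-2.0 inflate the row CV; per-spot
        normalization brings it back down."""
        rng = np.random.default_rng(2)
        factors = np.linspace(0.5, 2.0, 6)
        base = rng.poisson(200, size=(6, 8, 1)).astype(float)
        striped = (base * factors[:, None, None]).astype(int).reshape(-1, 1)
        y, x = np.divmod(np.arange(48), 8)
        mat = make_matrix(striped, x_idx=x, y_idx=y)
        pre, _ = stripe_metric(mat.counts, mat.spots)
        norm = normalize_spots(mat)
        post, _ = stripe_metric(norm, mat.spots)
        assert post < pre


@pytest.fixture(scope="module")
def records():
    rng = np.random.default_rng(3)
    rows = []
    rid = 0
    for spot in range(6):
        for _mol in range(40):
            umi = "".join(rng.choice(list("ACGT"), 10))
            gene = f"g{rng.integers(8)}"
            for _ in range(10):  # duplicate-heavy: 10 reads per molecule
                rows.append((f"r{rid}", "A1", spot, 0, gene, umi, "exonic"))
                rid += 1
    return pd.DataFrame(
        rows,
        columns=["read_id", "well_id", "x_idx", "y_idx", "gene", "umi", "region"],
    )


class TestSaturation:

    def test_full_fraction_equals_full_run(self, records):
        from xdbit.demux import digital_expression

        curve = subsample_saturation(records, [1.0], seed=0)
        full = digital_expression(records)
        assert curve.median_umis_per_spot[0] == full.spots["total_umis"].median()

    def test_monotone_and_saturated_at_half(self, records):
        """With 10 reads per molecule, half the reads still see nearly every
        molecule: expected recovery 1-(1-f)^d = 99.9% at f=0.5, d=10."""
        fractions = (0.1, 0.25, 0.5, 0.75, 1.0)
        for seed in range(3):
            curve = subsample_saturation(records, fractions, seed=seed)
            assert np.all(np.diff(curve.median_umis_per_spot) >= 0)
            assert np.all(np.diff(curve.median_genes_per_spot) >= 0)
            assert (
                curve.median_umis_per_spot[2] >= 0.85 * curve.median_umis_per_spot[-1]
            )

    def test_bad_fraction_rejected(self, records):
        with pytest.raises(ValueError):
            subsample_saturation(records, [0.0, 1.0], seed=0)


class TestMarkersAndPseudobulk:
    def test_marker_presence_extremes(self):
        mat = make_matrix(np.ones((2, 3)))
        present = marker_presence(mat, {"organ": ["G0", "g1", "g2"]})
        assert present["organ"] == 1.0
        absent = marker_presence(mat, {"other": ["nope1", "nope2"]})
        assert absent["other"] == 0.0
        with pytest.raises(ValueError):
            marker_presence(mat, {"empty": []})

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        mat = make_matrix(rng.poisson(5, size=(10, 50)))
        bulk = pd.DataFrame({"self": mat.pseudobulk()})
        r = pseudobulk_correlate(mat, bulk)
        assert r["self"] == pytest.approx(1.0)

    def test_independent_profiles_uncorrelated(self):
        rng = np.random.default_rng(5)
        mat = make_matrix(rng.poisson(5, size=(4, 1000)))
        bulk = pd.DataFrame(
            {"random": rng.poisson(5, size=1000)},
            index=mat.counts.columns,
        )
        r = pseudobulk_correlate(mat, bulk)
        assert abs(r["random"]) < 0.1

    def test_pseudobulk_is_exact_gene_total(self, sim):
        truth = sim["truth"]
        assert truth.pseudobulk().equals(truth.counts.sum(axis=0))

    def test_too_few_shared_genes_rejected(self):
        mat = make_matrix(np.ones((2, 3)))
        bulk = pd.DataFrame({"b": [1.0]}, index=["g0"])
        with pytest.raises(ValueError):
            pseudobulk_correlate(mat, bulk)
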