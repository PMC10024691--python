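"""Barcode extraction, Hamming correction, gene assignment, UMI collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdbit.demux import (
    CROSSTALK,
    INVALID_X,
    SHORT,
    VALID,
    BarcodeLegend,
    HammingMatcher,
    ReadLayout,
    ReadSegment,
    ToyReference,
    collapse_umis,
    correct_and_assign,
    default_read_layout,
    digital_expression,
    extract_barcodes,
    filter_crosstalk,
    hamming,
    reads_to_counts,
    rna_metrics,
)

# legend with pairwise Hamming distance >= 3 within each axis
LEGEND = BarcodeLegend(
    x={"AAAAAAAA": 0, "CCCCCCCC": 1, "GGGGGGGG": 2},
    y={"AAAATTTT": 0, "CCCCGGGG": 1, "TTTTAAAA": 2},
    z={"AAAACCCC": "A1", "GGGGTTTT": "A1", "CCCCAAAA": "B1"},
)

SIMPLE_LAYOUT = ReadLayout(
    (
        ReadSegment("umi", 0, 10),
        ReadSegment("x_barcode", 10, 8),
        ReadSegment("y_barcode", 18, 8),
    )
)


def brute_force_match(query, legend_axis, max_hamming):
    """Independent oracle: exhaustive minimum-distance search with ties."""
    dists = {seq: hamming(query, seq) for seq in legend_axis}
    best = min(dists.values())
    if best > max_hamming:
        return None
    winners = [v for s, v in legend_axis.items() if dists[s] == best]
    return winners[0] if len(winners) == 1 else None


class TestExtractBarcodes:
    def test_plain_substring_extraction(self):
        read = "ACGTACGTAC" + "AAAAAAAA" + "CCCCCCCC"
        raw = extract_barcodes(read, SIMPLE_LAYOUT)
        assert raw.umi == "ACGTACGTAC"
        assert raw.x_seq == "AAAAAAAA"
        assert raw.y_seq == "CCCCCCCC"
        assert raw.z_seq is None and not raw.short

    def test_short_read_flagged(self):
        raw = extract_barcodes("ACGT" * 6, SIMPLE_LAYOUT)  # 24 < 26 nt
        assert raw.short
        a = correct_and_assign(raw, LEGEND)
        assert a.status == SHORT

    def test_linker_segments_leave_barcodes_unchanged(self):
        """Interleaving linkers shifts offsets but not the extracted fields."""
        umi, x, y = "ACGTACGTAC", "AAAAAAAA", "CCCCCCCC"
        linker = "TGCATGCA"
        padded_layout = ReadLayout(
            (
                ReadSegment("umi", 0, 10),
                ReadSegment("x_barcode", 10, 8),
                ReadSegment("linker", 18, 8),
                ReadSegment("y_barcode", 26, 8),
            )
        )
        plain = extract_barcodes(umi + x + y, SIMPLE_LAYOUT)
        padded = extract_barcodes(umi + x + linker + y, padded_layout)
        assert (plain.umi, plain.x_seq, plain.y_seq) == (
            padded.umi, padded.x_seq, padded.y_seq,
        )


class TestCorrectAndAssign:
    def _assign(self, x, y, z=None):
        from xdbit.demux import RawBarcodeFields

        raw = RawBarcodeFields(umi="ACGTACGTAC", x_seq=x, y_seq=y, z_seq=z)
        return correct_and_assign(raw, LEGEND, max_hamming=1)

    def test_exact_match_valid(self):
        a = self._assign("AAAAAAAA", "CCCCGGGG", "CCCCAAAA")
        assert (a.status, a.x_idx, a.y_idx, a.well_id) == (VALID, 0, 1, "B1")

    def test_single_mismatch_corrected(self):
        a = self._assign("AAAAAAAT", "CCCCGGGG", "CCCCAAAA")
        assert a.status == VALID and a.x_idx == 0
        assert brute_force_match("AAAAAAAT", LEGEND.x, 1) == 0

    def test_two_mismatches_rejected(self):
        a = self._assign("AAAAAATT", "CCCCGGGG")
        assert a.status == INVALID_X
        assert brute_force_match("AAAAAATT", LEGEND.x, 1) is None

    def test_tie_at_minimal_distance_rejected(self):
        legend = BarcodeLegend(x={"AAAA": 0, "AATT": 1}, y={"CCCC": 0})
        m = HammingMatcher(legend.x, max_hamming=1)
        # AATA is distance 1 from both AAAA and AATT
        assert m.match("AATA") is None
        assert brute_force_match("AATA", legend.x, 1) is None

    @pytest.mark.parametrize("max_hamming", [0, 1, 2])
    def test_matcher_agrees_with_exhaustive_search(self, max_hamming):
        """Table lookup and linear scan both reproduce the brute-force
        minimum-Hamming decision on random queries."""
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        barcodes = ["".join(rng.choice(bases, 8)) for _ in range(8)]
        legend = {b: i for i, b in enumerate(dict.fromkeys(barcodes))}
        matcher = HammingMatcher(legend, max_hamming)
        for _ in range(2000):
            q = "".join(rng.choice(bases, 8))
            assert matcher.match(q) == brute_force_match(q, legend, max_hamming)


class TestCrosstalkFilter:
    def test_own_barcode_kept(self):
        a = self._valid("A1")
        assert filter_crosstalk(a, "A1").status == VALID

    def test_foreign_barcode_dropped(self):
        a = self._valid("B1")
        assert filter_crosstalk(a, "A1").status == CROSSTALK

    def test_no_z_passthrough(self):
        from xdbit.demux import BarcodeAssignment

        a = BarcodeAssignment("r", "ACGT", 0, 0, None, VALID)
        assert filter_crosstalk(a, "A1").status == VALID

    @staticmethod
    def _valid(well):
        from xdbit.demux import BarcodeAssignment

        return BarcodeAssignment("r", "ACGTACGTAC", 0, 0, well, VALID)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seq_a = "".join(rng.choice(bases, 200))
    seq_b = "".join(rng.choice(bases, 200))
    intron = "".join(rng.choice(bases, 120))
    shared = "".join(rng.choice(bases, 80))
    return ToyReference(
        [
            ("geneA", "tx1", "exonic", seq_a + shared),
            ("geneA", "int1", "intronic", intron),
            ("geneB", "tx1", "exonic", seq_b + shared),
        ],
        min_prefix=30,
    )


class TestGeneAssignment:

    def test_unique_substring_assigns(self, reference):
        seq = reference.records[0][3][50:100]
        assert reference.lookup(seq) == ("geneA", "exonic")

    def test_shared_sequence_unassigned(self, reference):
        shared_read = reference.records[0][3][-50:]  # in both geneA and geneB
        assert reference.lookup(shared_read) == (None, None)

    def test_intronic_flag_changes_totals(self, reference):
        records = pd.DataFrame(
            {
                "well_id": ["A1"] * 3,
                "x_idx": [1] * 3,
                "y_idx": [1] * 3,
                "gene": ["geneA"] * 3,
                "umi": ["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"],
                "region": ["exonic", "exonic", "intronic"],
            }
        )
        with_introns = digital_expression(records, include_intronic=True)
        without = digital_expression(records, include_intronic=False)
        assert int(with_introns.counts.sum().sum()) == 3
        assert int(without.counts.sum().sum()) == 2

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ToyReference([], min_prefix=30)


class TestUmiCollapse:
    def brute_force_clusters(self, umis):
        """Oracle: connected components of the Hamming-1 graph."""
        import networkx as nx

        uniq = sorted(set(umis))
        g = nx.Graph()
        g.add_nodes_from(uniq)
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                if hamming(a, b) <= 1:
                    g.add_edge(a, b)
        return nx.number_connected_components(g)

    @pytest.mark.parametrize(
        "umis, expected",
        [
            (["ACGT", "ACGT"], 1),  # exact duplicates
            (["ACGT", "TGCA"], 2),  # distance 4
            (["AAAA", "AAAT", "TTTT"], 2),  # chain of two + singleton
            (["AAAA", "AAAT", "AATT", "ATTT", "TTTT"], 1),  # full chain
        ],
    )
    def test_known_cluster_counts(self, umis, expected):
        assert collapse_umis(umis) == expected
        assert self.brute_force_clusters(umis) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=0, max_size=12
        )
    )
    def test_matches_graph_components_and_permutation_invariant(self, umis):
        n = collapse_umis(umis)
        assert n == self.brute_force_clusters(umis)
        assert n == collapse_umis(list(reversed(umis)))


class TestDigitalExpressionAndMetrics:
    def test_counts_from_grouped_reads(self):
        records = pd.DataFrame(
            {
                "well_id": ["A1"] * 4,
                "x_idx": [1, 1, 1, 2],
                "y_idx": [1, 1, 1, 1],
                "gene": ["g1", "g1", "g2", "g1"],
                "umi": ["AAAAAAAAAA", "AAAAAAAAAT", "CCCCCCCCCC", "GGGGGGGGGG"],
            }
        )
        mat = digital_expression(records)
        # two UMIs at distance 1 collapse to one count
        assert mat.counts.loc["A1_x01_y01", "g1"] == 1
        assert mat.counts.loc["A1_x01_y01", "g2"] == 1
        assert mat.counts.loc["A1_x02_y01", "g1"] == 1

    def test_metrics_per_spot_and_depth_normalisation(self):
        records = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(5)],
                "status": [VALID] * 5,
                "well_id": ["A1"] * 5,
                "x_idx": [1] * 5,
                "y_idx": [1] * 5,
                "gene": ["g1", "g1", "g2", "g2", "g3"],
                "umi": [
                    "AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "TTTTTTTTTT",
                    "ACACACACAC",
                ],
                "region": ["exonic"] * 5,
            }
        )
        mat = digital_expression(records)
        m = rna_metrics(records, mat, total_reads=2_000_000)
        assert m["median_umis_per_spot"] == 5
        assert m["median_genes_per_spot"] == 3
        # 5 UMIs from 2e6 reads -> 2.5 per 1e6; 500 from 2e6 -> 250 scales the same
        assert m["median_umis_per_spot_per_1e6_reads"] == pytest.approx(2.5)


class TestPipeline:
    def test_noise_free_roundtrip_reproduces_truth(self, sim, sim_fastq, sim_config):
        """Demultiplexing error-free reads returns the generator's
        ground-truth count matrix exactly, and statuses partition reads."""
        r1, r2 = sim_fastq
        matrix, metrics, records = reads_to_counts(
            r1, r2, sim["legend"],
            read_layout=sim["read_layout"],
            reference=sim["reference"],
            chip_layout=sim_config.layout,
        )
        assert matrix.equals_counts(sim["truth"])
        assert metrics["valid_fraction"] == 1.0
        assert sum(metrics["status_counts"].values()) == metrics["total_reads"]
        # per-spot UMI totals match the truth row sums
        truth_totals = sim["truth"].counts.sum(axis=1)
        for spot_id, total in matrix.spots["total_umis"].items():
            assert total == truth_totals[spot_id]

    def test_mtx_roundtrip(self, tmp_path, sim, sim_fastq, sim_config):
        from xdbit.demux import CountMatrix

        r1, r2 = sim_fastq
        matrix, _, _ = reads_to_counts(
            r1, r2, sim["legend"],
            read_layout=sim["read_layout"],
            reference=sim["reference"],
        )
        matrix.to_mtx(tmp_path / "mtx")
        back = CountMatrix.from_mtx(tmp_path / "mtx")
        assert back.equals_counts(matrix)

    def test_legend_csv_roundtrip(self, tmp_path, sim):
        path = tmp_path / "legend.csv"
        sim["legend"].to_csv(path)
        back = BarcodeLegend.from_csv(path)
        assert back.x == sim["legend"].x
        assert back.y == sim["legend"].y
        assert back.z == sim["legend"].z

    def test_anndata_export(self, sim, sim_fastq, sim_config):
        r1, r2 = sim_fastq
        matrix, _, _ = reads_to_counts(
            r1, r2, sim["legend"],
            read_layout=sim["read_layout"],
            reference=sim["reference"],
            chip_layout=sim_config.layout,
        )
        adata = matrix.to_anndata()
        assert adata.shape == matrix.counts.shape
        assert "spatial" in adata.obsm
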