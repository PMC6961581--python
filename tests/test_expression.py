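"""Exon assignment, RPKM, expression counting, PCA."""

import numpy as np
import pandas as pd
import pytest

from bagseq.expression import (
    ExonModel,
    assign_read_to_gene,
    count_expression,
    pca_and_markers,
    rpkm,
)


@pytest.fixture
def model():
    return ExonModel(
        pd.DataFrame(
            [
                {"gene": "G1", "transcript": "G1.t1", "chrom": "chr1", "strand": "+",
                 "exons": [(1000, 1400), (1700, 2100)]},
                {"gene": "G2", "transcript": "G2.t1", "chrom": "chr1", "strand": "+",
                 "exons": [(5000, 6000)]},
            ]
        )
    )


class TestAssignRead:
    def test_half_in_exon_counts_in_singlecell_mode(self, model):
        # 76-base read with exactly 38 bases inside the exon: boundary inclusive
        blocks = [(1362, 1438)]
        assert assign_read_to_gene("chr1", blocks, model, "singlecell", 76) == "G1"

    def test_just_under_half_not_counted(self, model):
        blocks = [(1363, 1439)]  # 37 exonic bases
        assert assign_read_to_gene("chr1", blocks, model, "singlecell", 76) is None

    def test_fully_intronic_read_unassigned_both_modes(self, model):
        blocks = [(1450, 1526)]
        assert assign_read_to_gene("chr1", blocks, model, "bulk") is None
        assert assign_read_to_gene("chr1", blocks, model, "singlecell", 76) is None

    def test_bulk_requires_complete_exonic_alignment(self, model):
        inside = [(1100, 1176)]
        straddle = [(1380, 1456)]
        assert assign_read_to_gene("chr1", inside, model, "bulk") == "G1"
        assert assign_read_to_gene("chr1", straddle, model, "bulk") is None
        # the same straddling read passes the 50% single-cell rule
        assert assign_read_to_gene("chr1", straddle, model, "singlecell", 76) is None

    def test_spliced_read_spanning_exons_counts_in_bulk(self, model):
        blocks = [(1360, 1400), (1700, 1736)]
        assert assign_read_to_gene("chr1", blocks, model, "bulk") == "G1"

    def test_two_gene_overlap_is_ambiguous(self):
        overlapping = ExonModel(
            pd.DataFrame(
                [
                    {"gene": "A", "transcript": "A.t", "chrom": "c", "strand": "+",
                     "exons": [(0, 500)]},
                    {"gene": "B", "transcript": "B.t", "chrom": "c", "strand": "-",
                     "exons": [(100, 600)]},
                ]
            )
        )
        assert assign_read_to_gene("c", [(200, 276)], overlapping, "singlecell", 76) is None


class TestRpkm:
    def test_formula(self):
        counts = pd.Series({"t1": 10})
        lengths = pd.Series({"t1": 1000})
        assert rpkm(counts, lengths, 1_000_000)["t1"] == pytest.approx(10.0)

    def test_gene_takes_max_transcript(self):
        m = ExonModel(
            pd.DataFrame(
                [
                    {"gene": "G", "transcript": "t1", "chrom": "c", "strand": "+",
                     "exons": [(0, 1000)]},
                    {"gene": "G", "transcript": "t2", "chrom": "c", "strand": "+",
                     "exons": [(0, 500)]},
                ]
            )
        )
        counts = pd.Series({"t1": 3, "t2": 7})
        lengths = m.transcript_lengths()
        values = rpkm(counts, lengths, 1_000_000, model=m)
        per_t = rpkm(counts, lengths, 1_000_000)
        assert values["G"] == pytest.approx(max(per_t))

    def test_zero_count_transcript_is_zero(self):
        out = rpkm(pd.Series({"t1": 0}), pd.Series({"t1": 500}), 1000)
        assert out["t1"] == 0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(pd.Series({"t1": 1}), pd.Series({"t1": 500}), 0)


class TestCountExpression:
    def test_templates_counted_once_per_gene(self, model):
        reads = pd.DataFrame(
            [
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 1100, "strand": "+"},
                {"bag": "c1", "tag": "t2", "chrom": "chr1", "pos": 1105, "strand": "+"},
                {"bag": "c1", "tag": "t3", "chrom": "chr1", "pos": 5100, "strand": "+"},
                {"bag": "c2", "tag": "t1", "chrom": "chr1", "pos": 5200, "strand": "+"},
            ]
        )
        m = count_expression(reads, model, read_length=76)
        assert m.loc["G1", "c1"] == 2
        assert m.loc["G2", "c1"] == 1
        assert m.loc["G2", "c2"] == 1
        assert m.loc["G1", "c2"] == 0

    def test_tag_on_two_genes_goes_to_better_supported(self, model):
        reads = pd.DataFrame(
            [
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 1100, "strand": "+"},
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 1120, "strand": "+"},
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 5100, "strand": "+"},
            ]
        )
        m = count_expression(reads, model, read_length=76)
        assert m.loc["G1", "c1"] == 1 and m.loc["G2", "c1"] == 0

    def test_tied_tag_dropped(self, model):
        reads = pd.DataFrame(
            [
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 1100, "strand": "+"},
                {"bag": "c1", "tag": "t1", "chrom": "chr1", "pos": 5100, "strand": "+"},
            ]
        )
        m = count_expression(reads, model, read_length=76)
        assert m["c1"].sum() == 0


def planted_two_population_matrix(rng, n_cells=30, n_genes=60, n_markers=10, fold=20):
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    base = np.full(n_genes, 10.0)
    data = np.empty((n_genes, n_cells))
    labels = []
    for j in range(n_cells):
        mean = base.copy()
        if j % 2 == 0:
            mean[:n_markers] *= fold
            labels.append("P0")
        else:
            mean[n_markers : 2 * n_markers] *= fold
            labels.append("P1")
        data[:, j] = rng.poisson(mean)
    return pd.DataFrame(data, index=genes, columns=cells), labels


class TestPca:
    def test_two_populations_separate_on_pc1(self, rng):
        matrix, labels = planted_two_population_matrix(rng)
        result = pca_and_markers(matrix)
        pc1 = result.coordinates["PC1"].to_numpy()
        a = pc1[np.array(labels) == "P0"]
        b = pc1[np.array(labels) == "P1"]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()
        # marker list contains the planted discriminating genes
        planted = {f"g{i}" for i in range(20)}
        assert len(planted & set(result.markers["gene"])) >= 15

    def test_duplicated_cells_have_identical_coordinates(self, rng):
        matrix, _ = planted_two_population_matrix(rng, n_cells=10)
        dup = matrix.copy()
        dup["c0_copy"] = matrix["c0"]
        result = pca_and_markers(dup)
        a = result.coordinates.loc["c0"].to_numpy()
        b = result.coordinates.loc["c0_copy"].to_numpy()
        assert np.allclose(a, b)

    def test_pure_noise_pc1_share_in_marchenko_pastur_range(self, rng):
        """One homogeneous population: PC1 carries no outsized variance."""
        G, C = 50, 100
        matrix = pd.DataFrame(
            rng.poisson(10.0, size=(G, C)),
            index=[f"g{i}" for i in range(G)],
            columns=[f"c{i}" for i in range(C)],
        )
        result = pca_and_markers(matrix)
        gamma = G / C
        lam_max = (1 + np.sqrt(gamma)) ** 2
        share = result.explained_variance_ratio[0]
        assert share < 1.6 * lam_max / G
        assert share > 1.0 / G  # PC1 always at least the average

    def test_cell_order_invariance_up_to_sign(self, rng):
        matrix, _ = planted_two_population_matrix(rng)
        shuffled = matrix.sample(frac=1.0, axis=1, random_state=5)
        a = pca_and_markers(matrix).coordinates["PC1"]
        b = pca_and_markers(shuffled).coordinates["PC1"].reindex(a.index)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8) or np.allclose(
            a.to_numpy(), -b.to_numpy(), atol=1e-8
        )

    def test_bulk_profiles_project_with_their_population(self, rng):
        matrix, labels = planted_two_population_matrix(rng)
        bulk = pd.DataFrame(
            {
                "bulk_P0": matrix.loc[:, np.array(labels) == "P0"].mean(axis=1),
                "bulk_P1": matrix.loc[:, np.array(labels) == "P1"].mean(axis=1),
            }
        )
        result = pca_and_markers(matrix, bulk=bulk)
        pc1 = result.coordinates["PC1"]
        centroid_p0 = pc1[np.array(labels) == "P0"].mean()
        b0 = result.bulk_coordinates.loc["bulk_P0", "PC1"]
        b1 = result.bulk_coordinates.loc["bulk_P1", "PC1"]
        assert abs(b0 - centroid_p0) < abs(b1 - centroid_p0)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            pca_and_markers(pd.DataFrame(np.ones((5, 2))))

    def test_constant_genes_dropped_and_reported(self, rng):
        matrix, _ = planted_two_population_matrix(rng, n_cells=10)
        matrix.loc["g0"] = 0.0
        result = pca_and_markers(matrix)
        assert "g0" in result.dropped_genes
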