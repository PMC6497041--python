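import numpy as np
import pandas as pd
import pytest

from cernakit.data_model import (
    ExpressionMatrix,
    InteractionTable,
    SampleTable,
    compute_fpkm,
    estimate_size_factors,
    log2_normalize,
    read_expression_matrix,
    read_gene_lengths,
    read_interactions,
    read_sample_table,
    write_expression_matrix,
    write_gene_lengths,
    write_interactions,
    write_sample_table,
)

from conftest import make_expression


class TestExpressionIO:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\tS1\tS2\nG1\t1\t2\nG2\t3\t4\nG3\t5\t6\n")
        em = read_expression_matrix(p, "mRNA", "counts")
        assert em.shape == (3, 2)
        assert em.gene_ids == ["G1", "G2", "G3"]
        assert em.values.loc["G2", "S2"] == 4

    def test_duplicate_gene_id_is_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\tS1\nG1\t1\nG1\t2\n")
        with pytest.raises(ValueError, match="G1"):
            read_expression_matrix(p, "mRNA", "counts")

    def test_duplicate_sample_id_is_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\tS1\tS1\nG1\t1\t2\n")
        with pytest.raises(ValueError, match="S1"):
            read_expression_matrix(p, "mRNA", "counts")

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene_id\tS1\tS2\nG1\t1\tx\n")
        with pytest.raises(ValueError, match="G1.*S2"):
            read_expression_matrix(p, "mRNA", "counts")

    def test_round_trip_identity(self, tmp_path, default_cohort):
        for em in (default_cohort.mrna, default_cohort.lncrna, default_cohort.mirna):
            p = tmp_path / f"{em.gene_class}.tsv"
            write_expression_matrix(em, p)
            back = read_expression_matrix(p, em.gene_class, em.unit)
            pd.testing.assert_frame_equal(back.values, em.values)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_expression([[1, -2]])


class TestSampleTable:
    def test_normal_and_tumor_accepted(self):
        st = SampleTable(
            pd.DataFrame(
                {"condition": ["normal", "tumor"], "stage": [np.nan, "T2"],
                 "os_time": [np.nan, 100.0], "os_event": [np.nan, 1.0]},
                index=pd.Index(["a", "b"], name="sample_id"),
            )
        )
        assert st.tumor_ids("T2") == ["b"]
        assert st.normal_ids() == ["a"]

    def test_tumor_missing_stage_rejected(self):
        with pytest.raises(ValueError, match="missing stage"):
            SampleTable(
                pd.DataFrame(
                    {"condition": ["tumor"], "stage": [np.nan], "os_time": [10.0], "os_event": [1.0]},
                    index=pd.Index(["a"], name="sample_id"),
                )
            )

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            SampleTable(
                pd.DataFrame(
                    {"condition": ["healthy"], "stage": [np.nan], "os_time": [np.nan], "os_event": [np.nan]},
                    index=pd.Index(["a"], name="sample_id"),
                )
            )

    def test_staged_normal_rejected(self):
        with pytest.raises(ValueError, match="normal"):
            SampleTable(
                pd.DataFrame(
                    {"condition": ["normal"], "stage": ["T1"], "os_time": [np.nan], "os_event": [np.nan]},
                    index=pd.Index(["a"], name="sample_id"),
                )
            )

    def test_round_trip(self, tmp_path, default_cohort):
        p = tmp_path / "samples.tsv"
        write_sample_table(default_cohort.samples, p)
        back = read_sample_table(p)
        pd.testing.assert_frame_equal(back.data, default_cohort.samples.data, check_dtype=False)

    def test_tumor_row_with_empty_stage_in_tsv_rejected(self, tmp_path):
        p = tmp_path / "samples.tsv"
        p.write_text("sample_id\tcondition\tstage\tos_time\tos_event\na\ttumor\t\t10\t1\n")
        with pytest.raises(ValueError, match="missing stage"):
            read_sample_table(p)


class TestInteractions:
    def test_duplicates_dropped_and_counted(self):
        df = pd.DataFrame(
            [["mir1", "g1", "mRNA", "db"], ["mir1", "g1", "mRNA", "db"], ["mir1", "g2", "mRNA", "db"]],
            columns=["mirna_id", "target_id", "target_class", "source"],
        )
        it = InteractionTable(df)
        assert len(it) == 2
        assert it.n_deduplicated == 1

    def test_inconsistent_target_class_rejected(self):
        df = pd.DataFrame(
            [["mir1", "g1", "mRNA", "db"], ["mir2", "g1", "lncRNA", "db"]],
            columns=["mirna_id", "target_id", "target_class", "source"],
        )
        with pytest.raises(ValueError, match="g1"):
            InteractionTable(df)

    def test_round_trip(self, tmp_path, default_cohort):
        p = tmp_path / "inter.tsv"
        write_interactions(default_cohort.interactions, p)
        back = read_interactions(p)
        pd.testing.assert_frame_equal(back.data, default_cohort.interactions.data)

    def test_lengths_round_trip(self, tmp_path, default_cohort):
        p = tmp_path / "len.tsv"
        write_gene_lengths(default_cohort.gene_lengths, p)
        back = read_gene_lengths(p)
        pd.testing.assert_series_equal(back, default_cohort.gene_lengths.astype(int), check_names=False)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        em = make_expression([[5, 5], [9, 9]])
        np.testing.assert_allclose(estimate_size_factors(em).to_numpy(), [1.0, 1.0])

    def test_hand_median_of_ratios(self):
        # genes x samples [[2,4],[6,12]]: every ratio to the geometric mean is
        # 1/sqrt(2) for sample 1 and sqrt(2) for sample 2
        em = make_expression([[2, 4], [6, 12]])
        sf = estimate_size_factors(em).to_numpy()
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_permutation_equivariance(self, default_cohort):
        em = default_cohort.mrna
        sf = estimate_size_factors(em)
        perm = em.sample_ids[::-1]
        sf_perm = estimate_size_factors(em.subset_samples(perm))
        np.testing.assert_allclose(sf_perm.to_numpy(), sf.loc[perm].to_numpy())

    def test_global_scaling_invariance(self):
        em = make_expression([[2, 4], [6, 12], [3, 5]])
        scaled = make_expression(em.values.to_numpy() * 7)
        np.testing.assert_allclose(
            estimate_size_factors(em).to_numpy(), estimate_size_factors(scaled).to_numpy()
        )

    def test_geometric_mean_is_one(self, default_cohort):
        sf = estimate_size_factors(default_cohort.lncrna).to_numpy()
        assert abs(np.log(sf).mean()) < 1e-12

    def test_no_zero_free_gene_is_an_error(self):
        em = make_expression([[0, 4], [6, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(em)


class TestFPKM:
    def test_direct_formula(self):
        # counts 10, length 1000 bp, library 1e6 -> FPKM 10
        em = make_expression([[10], [999990]], gene_ids=["G1", "G2"], sample_ids=["S1"])
        lengths = pd.Series([1000, 2000], index=["G1", "G2"])
        fpkm = compute_fpkm(em, lengths)
        assert fpkm.unit == "fpkm"
        assert fpkm.values.loc["G1", "S1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        em = make_expression([[0], [100]])
        fpkm = compute_fpkm(em, pd.Series([500, 500], index=["G0", "G1"]))
        assert fpkm.values.iloc[0, 0] == 0.0

    def test_depth_invariance(self):
        em = make_expression([[10, 20], [30, 40]])
        doubled = make_expression([[20, 20], [60, 40]])
        lengths = pd.Series([100, 300], index=["G0", "G1"])
        a = compute_fpkm(em, lengths).values
        b = compute_fpkm(doubled, lengths).values
        np.testing.assert_allclose(a["S0"], b["S0"])

    def test_missing_length_names_gene(self):
        em = make_expression([[1], [2]])
        with pytest.raises(ValueError, match="G1"):
            compute_fpkm(em, pd.Series([100], index=["G0"]))

    def test_column_sum_identity(self, default_cohort):
        em = default_cohort.mirna
        lengths = default_cohort.gene_lengths
        fpkm = compute_fpkm(em, lengths).values.to_numpy()
        counts = em.values.to_numpy()
        lens = lengths.loc[em.gene_ids].to_numpy(float)
        expected = 1e9 * (counts / lens[:, None]).sum(axis=0) / counts.sum(axis=0)
        np.testing.assert_allclose(fpkm.sum(axis=0), expected)


def test_log2_normalize_unit_and_values():
    em = make_expression([[3, 3], [7, 7]])
    out = log2_normalize(em)
    assert out.unit == "log2norm"
    np.testing.assert_allclose(out.values.to_numpy(), np.log2([[4, 4], [8, 8]]))
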