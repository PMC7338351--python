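"""Cohort data model, additive encoding, scaling and the TSV/VCF readers."""

import numpy as np
import pytest

from epiboost.cohort import (
    CohortError,
    GenotypeMatrix,
    MISSING_CODE,
    MinMaxScaler,
    SNPRecord,
    apply_minmax,
    assemble_features,
    encode_additive,
    filter_missing_snps,
    fit_minmax,
    read_genotypes,
    write_genotypes_tsv,
)


SNP = SNPRecord("rs1", "chr1", 100, "A", "G")


class TestAdditiveEncoding:
    @pytest.mark.parametrize(
        "call,expected",
        [("AA", 0), ("AG", 1), ("GA", 1), ("GG", 2)],
    )
    def test_minor_allele_count(self, call, expected):
        assert encode_additive(call, SNP) == expected

    def test_foreign_allele_rejected(self):
        with pytest.raises(CohortError, match="neither declared allele"):
            encode_additive("AT", SNP)

    @pytest.mark.parametrize("call", ["AA", "AG", "GG"])
    def test_orientation_complementarity(self, call):
        flipped = SNPRecord("rs1", "chr1", 100, "G", "A")
        assert encode_additive(call, SNP) + encode_additive(call, flipped) == 2

    def test_invalid_record_rejected(self):
        with pytest.raises(CohortError):
            SNPRecord("rs2", "chr1", 0, "A", "G")
        with pytest.raises(CohortError):
            SNPRecord("rs2", "chr1", 5, "A", "A")


def toy_matrix(codes) -> GenotypeMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    snps = [
        SNPRecord(f"rs{j}", "chr1", 10 * (j + 1), "A", "G")
        for j in range(codes.shape[1])
    ]
    return GenotypeMatrix(
        subjects=[f"S{i}" for i in range(codes.shape[0])], snps=snps, codes=codes
    )


class TestMissingSNPFilter:
    def test_single_missing_call_drops_the_column(self):
        codes = np.zeros((4, 10), dtype=np.int8)
        codes[2, 3] = MISSING_CODE
        filtered, removed = filter_missing_snps(toy_matrix(codes))
        assert filtered.n_snps == 9
        assert removed == 1
        assert "rs3" not in filtered.snp_ids

    def test_clean_matrix_unchanged(self):
        gm = toy_matrix([[0, 1], [2, 1], [1, 0]])
        filtered, removed = filter_missing_snps(gm)
        assert removed == 0
        np.testing.assert_array_equal(filtered.codes, gm.codes)
        assert filtered.subjects == gm.subjects

    def test_all_missing_warns_not_errors(self):
        codes = np.full((3, 2), MISSING_CODE, dtype=np.int8)
        with pytest.warns(UserWarning, match="0 SNPs retained"):
            filtered, removed = filter_missing_snps(toy_matrix(codes))
        assert filtered.n_snps == 0
        assert removed == 2

    def test_idempotent(self):
        codes = np.zeros((4, 5), dtype=np.int8)
        codes[0, 0] = MISSING_CODE
        once, _ = filter_missing_snps(toy_matrix(codes))
        twice, removed = filter_missing_snps(once)
        assert removed == 0
        np.testing.assert_array_equal(once.codes, twice.codes)


class TestMAF:
    def test_maf_formula_and_orientation_warning(self):
        gm = toy_matrix([[2, 0], [2, 1], [1, 0], [2, 1]])
        with pytest.warns(UserWarning, match="frequency > 0.5"):
            maf = gm.minor_allele_frequencies()
        np.testing.assert_allclose(maf, [7 / 8, 2 / 8])


class TestMinMax:
    def test_fit_stores_range(self):
        s = fit_minmax(np.array([2.0, 4.0, 6.0]))
        assert (s.vmin, s.vmax) == (2.0, 6.0)

    def test_fit_ignores_missing(self):
        s = fit_minmax(np.array([1.0, np.nan, 3.0]))
        assert (s.vmin, s.vmax) == (1.0, 3.0)

    def test_fit_all_missing_errors(self):
        with pytest.raises(CohortError):
            fit_minmax(np.array([np.nan, np.nan]))

    def test_degenerate_flag_and_zero_mapping(self):
        s = fit_minmax(np.array([5.0, 5.0]))
        assert s.degenerate
        np.testing.assert_array_equal(apply_minmax(s, np.array([5.0, 9.0])), [0.0, 0.0])

    @pytest.mark.parametrize(
        "value,expected", [(4.0, 0.5), (8.0, 1.0), (0.0, 0.0), (2.0, 0.0), (6.0, 1.0)]
    )
    def test_transform_and_clip(self, value, expected):
        s = MinMaxScaler(2.0, 6.0)
        assert apply_minmax(s, np.array([value]))[0] == expected

    def test_output_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        s = fit_minmax(rng.normal(size=50))
        out = apply_minmax(s, rng.normal(0, 10, size=500))
        assert np.all((out >= 0) & (out <= 1))


class TestAssembleFeatures:
    def test_column_order_and_shape(self, informative_cohort):
        cohort, _ = informative_cohort
        rows = np.arange(5)
        design = assemble_features(
            cohort, ["snp00002", "snp00001"], ["smoker"], rows, rows
        )
        assert design.X.shape == (5, 3)
        assert design.names == ["snp00002", "snp00001", "smoker"]
        assert [d.source for d in design.descriptors] == [
            "snp", "snp", "demographic",
        ]

    def test_demographic_only_design(self, informative_cohort):
        cohort, _ = informative_cohort
        rows = np.arange(10)
        names = [f.name for f in cohort.group_features("group1")]
        design = assemble_features(cohort, [], names, rows, rows)
        assert design.X.shape == (10, len(names))
        assert all(d.source == "demographic" for d in design.descriptors)

    def test_unknown_feature_errors(self, informative_cohort):
        cohort, _ = informative_cohort
        with pytest.raises(CohortError, match="unknown"):
            assemble_features(cohort, [], ["no_such_feature"], [0, 1], [0, 1])

    def test_scalers_fitted_on_source_not_target(self, informative_cohort):
        cohort, _ = informative_cohort
        src = np.arange(50)
        target = np.arange(50, 80)
        design = assemble_features(cohort, [], ["bmi"], target, src)
        col = design.X[:, 0]
        assert np.all((col >= 0) & (col <= 1))  # clipped against source range

    def test_deterministic(self, informative_cohort):
        cohort, _ = informative_cohort
        rows = np.arange(20)
        a = assemble_features(cohort, ["snp00001"], ["bmi"], rows, rows)
        b = assemble_features(cohort, ["snp00001"], ["bmi"], rows, rows)
        assert a.X.tobytes() == b.X.tobytes()


class TestGenotypeIO:
    def test_tsv_round_trip(self, tmp_path):
        gm = toy_matrix([[0, 1], [2, MISSING_CODE], [1, 0]])
        path = tmp_path / "geno.tsv"
        write_genotypes_tsv(gm, path)
        back = read_genotypes(path, "tabular")
        assert back.subjects == gm.subjects
        assert back.snp_ids == gm.snp_ids
        np.testing.assert_array_equal(back.codes, gm.codes)

    def test_allele_pair_cells(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text(
            "subject_id\trs1\ns1\tAA\ns2\tAG\ns3\tGG\ns4\tNA\ns5\tAA\n"
        )
        gm = read_genotypes(path, "tabular")
        np.testing.assert_array_equal(
            gm.codes[:, 0], [0, 1, 2, MISSING_CODE, 0]
        )
        # A is the more frequent allele -> declared major
        assert gm.snps[0].major_allele == "A"
        assert gm.snps[0].minor_allele == "G"

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text("subject_id\trs1\ns1\tAA\ns2\tA?\n")
        with pytest.raises(CohortError, match="rs1"):
            read_genotypes(path, "tabular")

    def test_vcf_gt_mapping(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\n"
            "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n"
        )
        gm = read_genotypes(vcf, "vcf")
        assert gm.subjects == ["s1", "s2", "s3", "s4"]
        assert gm.snps[0] == SNPRecord("rs1", "chr1", 100, "A", "G")
        np.testing.assert_array_equal(gm.codes[:, 0], [0, 1, 2, MISSING_CODE])

    def test_multiallelic_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\trs1\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(CohortError, match="multi-allelic"):
            read_genotypes(vcf, "vcf")


class TestCohortRoundTrip:
    def test_save_load_dir(self, tmp_path, informative_cohort):
        from epiboost.cohort import load_cohort_dir, save_cohort_dir

        cohort, _ = informative_cohort
        save_cohort_dir(cohort, tmp_path / "cohort")
        back = load_cohort_dir(tmp_path / "cohort")
        assert back.subjects == cohort.subjects
        np.testing.assert_array_equal(back.labels, cohort.labels)
        np.testing.assert_array_equal(
            back.genotypes.codes, cohort.genotypes.codes
        )
        assert [f.name for f in back.demographics] == [
            f.name for f in cohort.demographics
        ]
        for a, b in zip(back.demographics, cohort.demographics):
            assert (a.kind, a.group) == (b.kind, b.group)
            np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-12)


def test_vcf_write_read_round_trip(tmp_path):
    from epiboost.cohort import read_genotypes, write_genotypes_vcf

    gm = toy_matrix([[0, 1], [2, MISSING_CODE], [1, 0]])
    path = tmp_path / "cohort.vcf"
    write_genotypes_vcf(gm, path)
    back = read_genotypes(path, "vcf")
    assert back.subjects == gm.subjects
    assert back.snps == gm.snps
    np.testing.assert_array_equal(back.codes, gm.codes)
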