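import numpy as np
import pandas as pd
import pytest

from xcmax4 import (
    CaseControlData,
    CountTable,
    ValidationError,
    XciCoding,
    expand_counts,
    load_fixture,
    read_count_table,
    read_tabular,
    read_vcf,
    tabulate,
    validate,
)
from xcmax4.data import CANONICAL_CODINGS


class TestXciCoding:
    def test_canonical_codings_cover_the_four_xci_patterns(self):
        assert [(c.z1, c.z2) for c in CANONICAL_CODINGS] == [(0, 2), (1, 2), (2, 2), (1, 1)]
        assert [c.label for c in CANONICAL_CODINGS] == ["XCI-SN", "XCI-R", "XCI-SR", "XCI-E"]

    @pytest.mark.parametrize("gamma,label", [(0.0, "XCI-SN"), (1.0, "XCI-R"), (2.0, "XCI-SR")])
    def test_gamma_maps_to_skewness_coding(self, gamma, label):
        c = XciCoding.from_gamma(gamma)
        assert (c.z1, c.z2) == (gamma, 2)
        assert c.label == label

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            XciCoding.from_gamma(2.5)


class TestExpandCounts:
    def test_stage1_group_sizes(self, stage1):
        f, m = stage1.sex == 1, stage1.sex == 0
        case, ctrl = stage1.phenotype == 1, stage1.phenotype == 0
        assert stage1.n == 2941
        assert (f & case).sum() == 1115
        assert (m & case).sum() == 341
        assert (f & ctrl).sum() == 1127
        assert (m & ctrl).sum() == 358

    def test_row_order_deterministic(self):
        t = CountTable((1, 2, 1), (1, 1), (0, 1, 1), (0, 2))
        d = expand_counts(t)
        # cases before controls, females before males, genotype descending
        assert d.phenotype.tolist() == [1] * 6 + [0] * 4
        assert d.genotype.tolist() == [2, 1, 1, 0, 1, 0, 1, 0, 0, 0]
        assert d.sex.tolist() == [1, 1, 1, 1, 0, 0, 1, 1, 0, 0]

    def test_two_subject_identity(self):
        t = CountTable((1, 0, 0), (0, 0), (0, 0, 1), (0, 0))
        d = expand_counts(t)
        assert sorted(d.genotype.tolist()) == [0, 2]

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            expand_counts(CountTable((0, 0, 0), (0, 0), (0, 0, 0), (0, 0)))

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValidationError):
            CountTable((-1, 2, 1), (1, 1), (0, 1, 1), (0, 2))
        with pytest.raises(ValidationError):
            CountTable((1.5, 2, 1), (1, 1), (0, 1, 1), (0, 2))

    def test_roundtrip_expand_then_tabulate(self):
        t = CountTable((3, 5, 2), (4, 1), (2, 2, 2), (0, 3), label="rt")
        assert tabulate(expand_counts(t)) == CountTable(
            (3, 5, 2), (4, 1), (2, 2, 2), (0, 3), label="rt"
        )

    def test_pooled_expansion_adds_source_indicator(self):
        pooled = load_fixture("han_pooled")
        d = expand_counts(pooled)
        assert d.n == pooled.n_total == 2941 + 8072
        assert d.covariates.shape[1] == 3
        src = d.covariates[:, 2]
        assert set(np.unique(src)) == {0.0, 1.0}
        assert (src == 0).sum() == 2941


class TestFixtures:
    def test_stage1_counts_as_published(self):
        t = load_fixture("chu_stage1")
        # female case CC/TC/TT = 163/508/444 stored as aa/Aa/AA
        assert t.female_case == (444, 508, 163)
        assert t.risk_allele == "T"

    def test_gliwice_male_controls(self):
        t = load_fixture("szymanski_gliwice")
        assert t.male_control == (10, 20)  # (T, C) = (A, a)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            load_fixture("nope")


class TestValidate:
    def test_clean_stage1(self, stage1):
        rep = validate(stage1)
        assert rep.ok and rep.n == 2941 and rep.n_cases == 1456

    def test_monomorphic_flagged(self):
        d = CaseControlData(
            genotype=np.ones(20, dtype=int),
            sex=np.tile([0, 1], 10),
            phenotype=np.repeat([0, 1], 10),
            covariates=np.column_stack([np.ones(20), np.tile([0, 1], 10)]),
        )
        assert any("monomorphic" in f for f in validate(d).flags)

    def test_duplicated_covariate_column_flagged(self):
        sex = np.tile([0, 1], 10)
        d = CaseControlData(
            genotype=np.tile([0, 1], 10),
            sex=sex,
            phenotype=np.repeat([0, 1], 10),
            covariates=np.column_stack([np.ones(20), sex, sex]),
        )
        assert any("rank deficient" in f for f in validate(d).flags)

    def test_idempotent(self, stage1):
        assert validate(stage1) == validate(stage1)

    def test_structural_errors_raise_at_construction(self):
        with pytest.raises(ValidationError, match="female genotypes"):
            CaseControlData(
                genotype=[3, 0], sex=[1, 1], phenotype=[1, 0], covariates=np.ones((2, 1))
            )
        with pytest.raises(ValidationError, match="male genotypes"):
            CaseControlData(
                genotype=[2, 0], sex=[0, 1], phenotype=[1, 0], covariates=np.ones((2, 1))
            )
        with pytest.raises(ValidationError, match="case and one control"):
            CaseControlData(
                genotype=[1, 0], sex=[1, 1], phenotype=[1, 1], covariates=np.ones((2, 1))
            )


class TestReaders:
    def test_tabular_roundtrip_and_listwise_deletion(self, tmp_path):
        df = pd.DataFrame({
            "id": ["a", "b", "c", "d", "e"],
            "sex": [1, 0, 1, 0, 1],
            "phenotype": [1, 0, 1, 0, 0],
            "genotype": [2, 1, np.nan, 2, 0],  # c missing; d diploid-coded male
            "age": [30, 40, 50, 60, 70],
        })
        p = tmp_path / "d.csv"
        df.to_csv(p, index=False)
        d = read_tabular(p, covariates=["age"])
        assert d.n == 4
        assert d.n_dropped_missing == 1
        assert d.genotype.tolist() == [2, 1, 1, 0]  # male 2 -> 1 copy
        assert d.covariates.shape == (4, 3)

    def test_count_table_reader(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text(
            "group,AA,Aa,aa,A,a\n"
            "female_case,3,5,2,,\nmale_case,,,,4,1\n"
            "female_control,2,2,2,,\nmale_control,,,,0,3\n"
        )
        t = read_count_table(p)
        assert t.female_case == (3, 5, 2) and t.male_control == (0, 3)

    def test_vcf_reader_male_codings(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=X>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf1\tf2\tm1\tm2\tm3\n"
            "X\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t1\t1/1\t0/1\n"
        )
        info = pd.DataFrame({
            "sample": ["f1", "f2", "m1", "m2", "m3"],
            "sex": [1, 1, 0, 0, 0],
            "phenotype": [1, 0, 1, 0, 1],
        })
        d = read_vcf(vcf, info)
        # m3 is a heterozygous male call -> missing -> dropped
        assert d.n == 4
        assert d.genotype.tolist() == [1, 2, 1, 1]

    def test_vcf_risk_allele_override(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=X>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf1\tf2\n"
            "X\t100\trs1\tC\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        info = pd.DataFrame({"sample": ["f1", "f2"], "sex": [1, 1], "phenotype": [1, 0]})
        d_alt = read_vcf(vcf, info)
        d_ref = read_vcf(vcf, info, risk_allele="C")
        assert d_alt.genotype.tolist() == [1, 2]
        assert d_ref.genotype.tolist() == [1, 0]
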