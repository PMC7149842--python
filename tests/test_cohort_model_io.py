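import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geneburden.cohort_model_io import (
    CONTROL_CARRIER_COUNTS,
    CohortDataset,
    Consequence,
    GenePanel,
    Group,
    IndividualRecord,
    VariantRecord,
    build_reference_cohort,
    read_annotated_variants,
    read_cohort_tsv,
    read_gene_panel,
    read_vcf,
    write_burden_table,
    write_cohort_tsv,
)
from geneburden.errors import EmptyPanelError, InputValidationError, SchemaError
from geneburden.burden_stats import carrier_count
from geneburden.oligogenic_analysis import genes_hit_per_individual, multigene_carriers

HEADER = "chrom\tpos\tref\talt\tgene\tconsequence\ttranscript\thgvs_c\thgvs_p\texac_af\tgnomad_af\tcarriers\n"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

class TestVariantRecord:
    def test_rejects_nonpositive_pos(self):
        with pytest.raises(ValueError, match="pos"):
            VariantRecord("1", 0, "A", "G", "GENE1", Consequence.MISSENSE)

    def test_rejects_ref_equals_alt(self):
        with pytest.raises(ValueError, match="identical"):
            VariantRecord("1", 5, "A", "A", "GENE1", Consequence.MISSENSE)

    def test_rejects_af_out_of_range(self):
        with pytest.raises(ValueError, match="out of"):
            VariantRecord("1", 5, "A", "G", "GENE1", Consequence.MISSENSE,
                          external_afs={"ExAC": 1.5})

    def test_consequence_parse_lists_enum(self):
        with pytest.raises(ValueError, match="missense"):
            Consequence.parse("gibberish")


class TestCohortDataset:
    def test_shape_mismatch(self):
        inds = [IndividualRecord("a", Group.CASE)]
        with pytest.raises(ValueError, match="shape"):
            CohortDataset(inds, [], np.zeros((2, 1), dtype=np.int8))

    def test_duplicate_variant_keys_rejected(self):
        inds = [IndividualRecord("a", Group.CASE)]
        v = VariantRecord("1", 5, "A", "G", "GENE1", Consequence.MISSENSE)
        with pytest.raises(ValueError, match="duplicate"):
            CohortDataset(inds, [v, v], np.zeros((1, 2), dtype=np.int8))

    def test_duplicate_individuals_rejected(self):
        inds = [IndividualRecord("a", Group.CASE), IndividualRecord("a", Group.CONTROL)]
        with pytest.raises(ValueError, match="duplicate individual"):
            CohortDataset(inds, [], np.zeros((2, 0), dtype=np.int8))


class TestGenePanel:
    def test_case_normalization_dedup(self):
        assert len(GenePanel("p", ["bAz1b", "BAZ1B"])) == 1

    def test_membership_case_insensitive(self):
        assert "baz1b" in GenePanel("p", ["BAZ1B"])


# --------------------------------------------------------------------------
# annotated-variant TSV
# --------------------------------------------------------------------------

class TestReadAnnotatedVariants:
    def test_basic_row(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER + "7\t72912871\tA\tG\tBAZ1B\tmissense\t.\tc.527A>G\t.\t0.0000082\t.\tCS216\n")
        (av,) = read_annotated_variants(path)
        assert av.record.external_afs == {"ExAC": 0.0000082}
        assert av.record.gene_symbol == "BAZ1B"
        assert av.carriers == {"CS216": 1}

    def test_novel_cell_means_absent(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER + "1\t10\tA\tG\tG1\tmissense\t.\t.\t.\tNovel\t0.0001\t.\n")
        (av,) = read_annotated_variants(path)
        assert "ExAC" not in av.record.external_afs
        assert av.record.external_afs["gnomAD"] == 0.0001

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER)
        assert read_annotated_variants(path) == []

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("chrom\tpos\tref\talt\tgene\n1\t10\tA\tG\tG1\n")
        with pytest.raises(SchemaError, match="consequence"):
            read_annotated_variants(path)

    def test_af_out_of_range_reports_row(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER + "1\t10\tA\tG\tG1\tmissense\t.\t.\t.\t2.0\t.\t.\n")
        with pytest.raises(InputValidationError, match="row 2"):
            read_annotated_variants(path)

    def test_unknown_consequence_lists_enum(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER + "1\t10\tA\tG\tG1\tweird\t.\t.\t.\t.\t.\t.\n")
        with pytest.raises(InputValidationError, match="synonymous"):
            read_annotated_variants(path)

    def test_hom_suffix(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(HEADER + "1\t10\tA\tG\tG1\tmissense\t.\t.\t.\t.\t.\tI1:hom;I2\n")
        (av,) = read_annotated_variants(path)
        assert av.carriers == {"I1": 2, "I2": 1}


# --------------------------------------------------------------------------
# gene panel files
# --------------------------------------------------------------------------

class TestReadGenePanel:
    def test_known_genes(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("GDF6\nMEOX1\nGDF3\nMYO18B\nRIPPLY2\n")
        panel = read_gene_panel(path)
        assert len(panel) == 5
        assert "MYO18B" in panel

    def test_normalization(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("bAz1b\nBAZ1B\n")
        assert len(read_gene_panel(path)) == 1

    def test_comments_only_errors(self, tmp_path):
        path = tmp_path / "panel.txt"
        path.write_text("# nothing\n# here\n")
        with pytest.raises(EmptyPanelError):
            read_gene_panel(path)


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
)


@pytest.fixture
def roster3():
    return [
        IndividualRecord("S1", Group.CASE),
        IndividualRecord("S2", Group.CONTROL),
        IndividualRecord("S3", Group.CONTROL),
    ]


@pytest.fixture
def empty_annotations(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(HEADER)
    return path


class TestReadVcf:
    def test_gt_dosage_mapping(self, tmp_path, roster3, empty_annotations):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n")
        cohort = read_vcf(vcf, empty_annotations, roster3)
        assert cohort.dosages[:, 0].tolist() == [1, 0, 2]

    def test_multiallelic_split(self, tmp_path, roster3, empty_annotations):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(VCF_HEADER + "1\t100\t.\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\n")
        cohort = read_vcf(vcf, empty_annotations, roster3)
        assert cohort.n_variants == 2
        assert [v.alt for v in cohort.variants] == ["A", "T"]
        assert cohort.dosages[:, 0].tolist() == [1, 0, 1]
        assert cohort.dosages[:, 1].tolist() == [0, 1, 1]

    def test_missing_genotype_is_reference(self, tmp_path, roster3, empty_annotations):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n")
        cohort = read_vcf(vcf, empty_annotations, roster3)
        assert cohort.dosages[:, 0].tolist() == [0, 1, 0]

    def test_no_variant_lines(self, tmp_path, roster3, empty_annotations):
        vcf = tmp_path / "a.vcf"
        vcf.write_text(VCF_HEADER)
        cohort = read_vcf(vcf, empty_annotations, roster3)
        assert cohort.n_variants == 0

    def test_annotation_join(self, tmp_path, roster3):
        ann = tmp_path / "ann.tsv"
        ann.write_text(HEADER + "1\t100\tA\tG\tBAZ1B\tmissense\t.\t.\t.\t0.00001\t.\t.\n")
        vcf = tmp_path / "a.vcf"
        vcf.write_text(
            VCF_HEADER
            + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
            + "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        )
        cohort = read_vcf(vcf, ann, roster3)
        assert cohort.variants[0].gene_symbol == "BAZ1B"
        assert cohort.variants[1].consequence is Consequence.OTHER


# --------------------------------------------------------------------------
# packaged reference cohort
# --------------------------------------------------------------------------

class TestReferenceCohort:
    def test_group_sizes(self, reference_cohort):
        assert reference_cohort.group_size(Group.CASE) == 37
        assert reference_cohort.group_size(Group.CONTROL) == 534

    @pytest.mark.parametrize(
        "gene,case_expected",
        [("BAZ1B", 3), ("FREM2", 3), ("SUFU", 2), ("VANGL1", 2), ("KMT2D", 3)],
    )
    def test_case_carrier_counts(self, reference_cohort, qualifying, gene, case_expected):
        assert carrier_count(reference_cohort, gene, Group.CASE, qualifying) == case_expected

    @pytest.mark.parametrize("gene,expected", sorted(CONTROL_CARRIER_COUNTS.items()))
    def test_control_carrier_counts(self, reference_cohort, qualifying, gene, expected):
        assert carrier_count(reference_cohort, gene, Group.CONTROL, qualifying) == expected

    def test_multigene_marginals(self, reference_cohort, qualifying, panel96):
        hits = genes_hit_per_individual(reference_cohort, qualifying, panel96)
        assert len(multigene_carriers(hits, Group.CASE)) == 7
        assert len(multigene_carriers(hits, Group.CONTROL)) == 30

    def test_pure_function_of_seed(self):
        assert build_reference_cohort(5) == build_reference_cohort(5)

    def test_seed_changes_only_control_identities(self, reference_cohort, qualifying, panel96):
        other = build_reference_cohort(99)
        assert other != reference_cohort
        from geneburden.qualifying_filter import FilterConfig, select_qualifying

        other_q = select_qualifying(other, FilterConfig(), panel96)
        for gene, expected in CONTROL_CARRIER_COUNTS.items():
            assert carrier_count(other, gene, Group.CONTROL, other_q) == expected


# --------------------------------------------------------------------------
# writers + round trips
# --------------------------------------------------------------------------

class TestWriters:
    def test_cohort_round_trip_fixture(self, reference_cohort, tmp_path):
        write_cohort_tsv(reference_cohort, tmp_path / "v.tsv", tmp_path / "r.tsv")
        back = read_cohort_tsv(tmp_path / "v.tsv", tmp_path / "r.tsv")
        assert np.array_equal(back.dosages, reference_cohort.dosages)
        assert [v.consequence for v in back.variants] == [
            v.consequence for v in reference_cohort.variants
        ]
        for original, reread in zip(reference_cohort.variants, back.variants):
            for source, af in original.external_afs.items():
                assert reread.external_afs[source] == pytest.approx(af, rel=1e-9)

    def test_burden_table_round_trip(self, reference_cohort, panel96, qualifying, tmp_path):
        from geneburden.burden_stats import gene_burden_scan

        results = gene_burden_scan(reference_cohort, panel96, qualifying)
        path = tmp_path / "burden.tsv"
        write_burden_table(results, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 96  # header + one row per panel gene
        header = lines[0].split("\t")
        for res, line in zip(results, lines[1:]):
            row = dict(zip(header, line.split("\t")))
            assert row["gene"] == res.gene_symbol
            assert int(row["case_carriers"]) == res.table.a
            assert int(row["control_carriers"]) == res.table.c

    def test_single_result_two_lines(self, tmp_path):
        from geneburden.burden_stats import GeneBurdenResult, TwoByTwo

        result = GeneBurdenResult("G1", TwoByTwo(1, 9, 0, 10), 1.05, 0.3, 0.5, 1.0)
        write_burden_table([result], tmp_path / "b.tsv")
        assert len((tmp_path / "b.tsv").read_text().splitlines()) == 2

    def test_empty_requires_flag(self, tmp_path):
        with pytest.raises(ValueError):
            write_burden_table([], tmp_path / "b.tsv")


# hypothesis round-trip over small random cohorts
_genes = st.sampled_from(["GENE1", "GENE2", "GENE3"])
_consequences = st.sampled_from([c for c in Consequence])


@st.composite
def small_cohorts(draw):
    n_ind = draw(st.integers(2, 5))
    n_var = draw(st.integers(0, 4))
    individuals = [
        IndividualRecord(f"I{i}", Group.CASE if i == 0 else Group.CONTROL)
        for i in range(n_ind)
    ]
    variants = []
    for j in range(n_var):
        afs = {}
        if draw(st.booleans()):
            afs["ExAC"] = draw(st.floats(0, 1, allow_nan=False))
        if draw(st.booleans()):
            afs["gnomAD"] = draw(st.floats(0, 1, allow_nan=False))
        variants.append(
            VariantRecord(
                chrom="1", pos=j + 1, ref="A", alt="G",
                gene_symbol=draw(_genes), consequence=draw(_consequences),
                external_afs=afs,
            )
        )
    dosages = np.array(
        [[draw(st.integers(0, 2)) for _ in range(n_var)] for _ in range(n_ind)],
        dtype=np.int8,
    ).reshape(n_ind, n_var)
    return CohortDataset(individuals, variants, dosages)


@settings(max_examples=30, deadline=None)
@given(cohort=small_cohorts())
def test_round_trip_property(cohort, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rt")
    write_cohort_tsv(cohort, tmp / "v.tsv", tmp / "r.tsv")
    back = read_cohort_tsv(tmp / "v.tsv", tmp / "r.tsv")
    assert np.array_equal(back.dosages, cohort.dosages)
    assert [v.consequence for v in back.variants] == [v.consequence for v in cohort.variants]
    for original, reread in zip(cohort.variants, back.variants):
        assert set(original.external_afs) == set(reread.external_afs)
        for source, af in original.external_afs.items():
            assert reread.external_afs[source] == pytest.approx(af, rel=1e-9, abs=1e-300)
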