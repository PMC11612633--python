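"""VCF cohort reading, variant classification, gene assignment, comparison."""

import itertools

import pytest

from neurovar import fixtures as fx
from neurovar.variants import (
    Carriage,
    CohortLayoutError,
    GeneRegion,
    GeneRegionIndex,
    VariantClass,
    VariantRecord,
    assign_gene,
    build_cohort_table,
    classify_variant,
    load_regions_bed,
    read_cohort_dir,
    variant_report,
)

BASES = "ACGT"


def brute_force_vclass(ref: str, alt: str) -> VariantClass:
    """Independent restatement: SNP = 1bp ACGT substitution; INDEL = plain
    alleles of unequal length; everything else OTHER."""
    plain = set("ACGTN")
    if set(ref) - plain or set(alt) - plain:
        return VariantClass.OTHER
    if len(ref) == 1 == len(alt):
        return VariantClass.SNP if ref in BASES and alt in BASES else VariantClass.OTHER
    if len(ref) != len(alt):
        return VariantClass.INDEL
    return VariantClass.OTHER


class TestClassifyVariant:
    def test_exhaustive_up_to_length_3(self):
        alleles = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product(BASES, repeat=n)
        ]
        for ref, alt in itertools.product(alleles, repeat=2):
            if ref == alt:
                continue
            assert classify_variant(ref, alt) is brute_force_vclass(ref, alt), (ref, alt)

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", VariantClass.SNP),
            ("AT", "A", VariantClass.INDEL),
            ("A", "ATT", VariantClass.INDEL),
            ("AG", "CT", VariantClass.OTHER),   # MNP
            ("A", "N", VariantClass.OTHER),     # N-containing single base
            ("N", "A", VariantClass.OTHER),
            ("A", "<DEL>", VariantClass.OTHER),  # symbolic
            ("A", "G[chr2:123[", VariantClass.OTHER),  # breakend
            ("A", "*", VariantClass.OTHER),     # spanning deletion
        ],
    )
    def test_declared_cases(self, ref, alt, expected):
        assert classify_variant(ref, alt) is expected

    def test_empty_or_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("", "A")
        with pytest.raises(ValueError):
            classify_variant("A", "")
        with pytest.raises(ValueError):
            classify_variant("A", "A")


class TestRegions:
    def test_bed_is_converted_to_1_based_inclusive(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t99\t200\tFUS\n# comment\n", encoding="utf-8")
        (reg,) = load_regions_bed(bed)
        assert (reg.start, reg.end, reg.gene_symbol) == (100, 200, "FUS")

    def test_bed_too_few_columns(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t10\n", encoding="utf-8")
        with pytest.raises(ValueError, match="4 BED columns"):
            load_regions_bed(bed)

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            GeneRegion(gene_symbol="G", chrom="chr1", start=10, end=5)


def mkvar(chrom="chr1", pos=150, ref="A", alt="G"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         vclass=classify_variant(ref, alt))


class TestAssignGene:
    REGIONS = [
        GeneRegion("FUS", "chr1", 100, 200),
        GeneRegion("NESTED", "chr1", 140, 160),
        GeneRegion("AAA", "chr1", 300, 400),
        GeneRegion("BBB", "chr1", 300, 400),
    ]

    def test_single_hit(self):
        assert assign_gene(mkvar(pos=120), self.REGIONS) == "FUS"

    def test_boundaries_inclusive(self):
        assert assign_gene(mkvar(pos=100), self.REGIONS[:1]) == "FUS"
        assert assign_gene(mkvar(pos=200), self.REGIONS[:1]) == "FUS"
        assert assign_gene(mkvar(pos=201), self.REGIONS[:1]) is None

    def test_absent_chromosome(self):
        assert assign_gene(mkvar(chrom="chrX"), self.REGIONS) is None

    def test_nested_interval_wins(self):
        assert assign_gene(mkvar(pos=150), self.REGIONS) == "NESTED"

    def test_equal_size_tie_breaks_lexicographically(self):
        assert assign_gene(mkvar(pos=350), self.REGIONS) == "AAA"

    def test_prebuilt_index_equivalent(self):
        idx = GeneRegionIndex(self.REGIONS)
        for pos in (100, 150, 250, 350):
            assert assign_gene(mkvar(pos=pos), idx) == assign_gene(mkvar(pos=pos), self.REGIONS)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=1000000>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)


def write_vcf(path, sample, lines):
    path.write_text(VCF_HEADER.format(sample=sample) + "".join(l + "\n" for l in lines),
                    encoding="utf-8")


def make_root(tmp_path, controls, patients):
    root = tmp_path / "cohort"
    for sub, cohort in (("controls", controls), ("patients", patients)):
        (root / sub).mkdir(parents=True)
        for sample, lines in cohort.items():
            write_vcf(root / sub / f"{sample}.vcf", sample, lines)
    return root


class TestReadCohortDir:
    def test_reads_both_cohorts(self, tmp_path):
        root = make_root(
            tmp_path,
            {"C1": ["chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1"], "C2": []},
            {"P1": [], "P2": []},
        )
        controls, patients = read_cohort_dir(root)
        assert set(controls) == {"C1", "C2"} and set(patients) == {"P1", "P2"}
        (rec,) = controls["C1"]
        assert rec.carriers == {"C1": Carriage.CARRIES}

    def test_multiallelic_split(self, tmp_path):
        root = make_root(
            tmp_path,
            {"C1": ["chr1\t150\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2"]},
            {"P1": []},
        )
        controls, _ = read_cohort_dir(root)
        recs = controls["C1"]
        assert [(r.pos, r.alt) for r in recs] == [(150, "G"), (150, "T")]
        assert all(r.carriers["C1"] is Carriage.CARRIES for r in recs)

    def test_genotype_carriage_states(self, tmp_path):
        root = make_root(
            tmp_path,
            {"C1": [
                "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0",
                "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t./.",
                "chr1\t300\t.\tA\tG\t.\tPASS\t.\tGT\t./1",  # half-missing carries
                "chr1\t400\t.\tA\tG\t.\tPASS\t.\tGT\t1/1",
            ]},
            {"P1": []},
        )
        controls, _ = read_cohort_dir(root)
        states = {r.pos: r.carriers["C1"] for r in controls["C1"]}
        assert states == {
            100: Carriage.DOES_NOT_CARRY,
            200: Carriage.MISSING,
            300: Carriage.CARRIES,
            400: Carriage.CARRIES,
        }

    def test_symbolic_alt_is_other(self, tmp_path):
        root = make_root(
            tmp_path,
            {"C1": ["chr1\t150\t.\tA\t<DEL>\t.\tPASS\t.\tGT\t0/1"]},
            {"P1": []},
        )
        controls, _ = read_cohort_dir(root)
        assert controls["C1"][0].vclass is VariantClass.OTHER

    def test_missing_patients_folder(self, tmp_path):
        root = tmp_path / "cohort"
        (root / "controls").mkdir(parents=True)
        write_vcf(root / "controls" / "C1.vcf", "C1", [])
        with pytest.raises(CohortLayoutError, match="patients"):
            read_cohort_dir(root)

    def test_duplicate_sample_name_rejected(self, tmp_path):
        root = make_root(tmp_path, {"C1": []}, {"P1": []})
        write_vcf(root / "controls" / "extra.vcf", "C1", [])
        with pytest.raises(CohortLayoutError, match="C1"):
            read_cohort_dir(root)

    def test_gene_tag_fast_path(self, tmp_path):
        root = tmp_path / "cohort"
        (root / "controls").mkdir(parents=True)
        (root / "patients").mkdir()
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000000>\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tC1\n"
            "chr1\t150\t.\tA\tG\t.\tPASS\tGENE=fus\tGT\t0/1\n"
        )
        (root / "controls" / "C1.vcf").write_text(header, encoding="utf-8")
        write_vcf(root / "patients" / "P1.vcf", "P1", [])
        controls, _ = read_cohort_dir(root, gene_tag="GENE")
        assert controls["C1"][0].gene_symbol == "FUS"


class TestBuildCohortTable:
    REGIONS = [GeneRegion("DAO", "chr1", 100, 500)]

    def cohort(self, tmp_path):
        # one SNP in DAO carried by 2/3 patients and 0/3 controls
        snp = "chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1"
        return make_root(
            tmp_path,
            {"C1": [], "C2": [], "C3": []},
            {"P1": [snp], "P2": [snp], "P3": []},
        )

    def test_planted_snp_recounted(self, tmp_path):
        controls, patients = read_cohort_dir(self.cohort(tmp_path))
        (row,) = build_cohort_table(controls, patients, self.REGIONS, {"DAO"}, "snp")
        assert (row.patient_carriers, row.patient_total) == (2, 3)
        assert (row.control_carriers, row.control_total) == (0, 3)
        assert row.status == "patient_only"
        assert row.gene_symbol == "DAO" and row.vclass is VariantClass.SNP

    def test_indel_view_empty_when_only_snps_planted(self, tmp_path):
        controls, patients = read_cohort_dir(self.cohort(tmp_path))
        assert build_cohort_table(controls, patients, self.REGIONS, {"DAO"}, "indel") == []

    def test_variant_outside_regions_excluded(self, tmp_path):
        root = make_root(
            tmp_path,
            {"C1": []},
            {"P1": ["chr1\t9999\t.\tA\tG\t.\tPASS\t.\tGT\t0/1"]},
        )
        controls, patients = read_cohort_dir(root)
        assert build_cohort_table(controls, patients, self.REGIONS, {"DAO"}, "snp") == []

    def test_gene_not_in_panel_excluded(self, tmp_path):
        controls, patients = read_cohort_dir(self.cohort(tmp_path))
        assert build_cohort_table(controls, patients, self.REGIONS, {"FUS"}, "snp") == []

    def test_cohort_swap_symmetry(self, tmp_path):
        fixture = fx.make_case_study_fixture(tmp_path / "fix", seed=11)
        controls, patients = read_cohort_dir(fixture["cohort"])
        regions = fixture["manifest_obj"].regions
        genes = {r.gene_symbol for r in regions}
        fwd = build_cohort_table(controls, patients, regions, genes, "snp")
        rev = build_cohort_table(patients, controls, regions, genes, "snp")
        assert len(fwd) == len(rev)
        flip = {"patient_only": "control_only", "control_only": "patient_only",
                "shared": "shared"}
        for a, b in zip(fwd, rev):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            assert (a.control_carriers, a.patient_carriers) == (
                b.patient_carriers, b.control_carriers)
            assert b.status == flip[a.status]

    def test_snp_indel_views_disjoint_and_idempotent(self, tmp_path):
        regions = fx.default_gene_regions()
        spec = fx.random_plant_spec(regions, 2, 2, seed=5)
        root, _ = fx.make_cohort_fixture(regions, spec, 2, 2, seed=5,
                                         root=tmp_path / "fix")
        genes = {r.gene_symbol for r in regions}
        controls, patients = read_cohort_dir(root)
        snps = build_cohort_table(controls, patients, regions, genes, "snp")
        indels = build_cohort_table(controls, patients, regions, genes, "indel")
        keys = lambda rows: {(r.chrom, r.pos, r.ref, r.alt, r.vclass) for r in rows}
        assert not (keys(snps) & keys(indels))
        # re-reading the directory reproduces the identical table
        controls2, patients2 = read_cohort_dir(root)
        assert build_cohort_table(controls2, patients2, regions, genes, "snp") == snps

    def test_invalid_vtype_rejected(self):
        with pytest.raises(ValueError):
            build_cohort_table({}, {}, [], set(), "other")


class TestVariantReport:
    def test_empty(self):
        assert variant_report([]) == {"n_variants": 0, "n_genes": 0, "per_gene": {}}

    def test_per_gene_counts_conserve_total(self, case_study):
        controls, patients = read_cohort_dir(case_study["cohort"])
        manifest = case_study["manifest_obj"]
        genes = {r.gene_symbol for r in manifest.regions}
        table = build_cohort_table(controls, patients, manifest.regions, genes, "snp")
        rep = variant_report(table)
        assert sum(rep["per_gene"].values()) == rep["n_variants"] == 23
        assert rep["n_genes"] == 7
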