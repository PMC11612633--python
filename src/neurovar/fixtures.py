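"""Synthetic catalogs, DE tables, and VCF cohorts with ground-truth manifests.

Real inputs to this pipeline come from curated gene-validity databases,
upstream RNA-seq differential-expression runs, and variant calling on
patient/control cohorts.  None of those are needed for testing: this module
plants known biomarker facts, known DE calls, and known variants (with exact
carrier assignments) into files of the same formats, and records the ground
truth in a machine-readable :class:`FixtureManifest` so every pipeline stage
can be checked against it.

The ``case-study-shape`` preset emulates the structure of a published ALS
cohort analysis: a DE table over ~20k genes in which exactly 1 of 21
biomarker panel genes is differentially expressed (TUBA4A), and small
control/patient VCF cohorts in which 23 SNPs and no indels fall across 7
biomarker genes (DAO, FIG4, ERBB4, TUBA4A, KIF5A, C9ORF72, TBK1) while
FUS, TARDBP and SOD1 carry no small variants at all.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from neurovar.catalog import (
    ALL_SUBTYPES,
    BiomarkerCatalog,
    BiomarkerRecord,
    load_catalog,
    save_catalog,
)
from neurovar.expression import DEClass, ExpressionRecord, ThresholdConfig, classify_expression
from neurovar.variants import GeneRegion, VariantClass, classify_variant

# ---------------------------------------------------------------------------
# Catalog facts
# ---------------------------------------------------------------------------

ALS = "Amyotrophic lateral sclerosis"

#: Curated ALS gene -> subtype assignments carried by the mini-catalog.
ALS_BIOMARKERS: tuple[tuple[str, str], ...] = (
    ("SOD1", "type 1"),
    ("C9ORF72", "type 1"),
    ("TBK1", "type 4"),
    ("FUS", "type 6"),
    ("TARDBP", "type 10"),
    ("FIG4", "type 11"),
    ("ERBB4", "type 19"),
    ("TUBA4A", "type 22"),
    ("KIF5A", "type 25"),
    ("DAO", ALL_SUBTYPES),
)

#: Neurological disease syndromes covered by the catalog.
NEUROLOGICAL_SYNDROMES: tuple[str, ...] = (
    "Epilepsy",
    ALS,
    "Intellectual disability",
    "Autism spectrum disorder",
    "Brain malformation syndrome",
    "Syndromic disorders",
    "Cerebral palsy",
    "RASopathy",
    "Aminoacidopathy",
    "Craniofacial malformations",
    "Parkinson's disease",
    "PHARC syndrome",
)

#: Non-neurological diseases with neurological manifestations.
NON_NEUROLOGICAL_SYNDROMES: tuple[str, ...] = (
    "Peroxisomal disorders",
    "Hereditary cancer",
    "Mitochondrial disease",
    "Retina-related disorders",
    "General gene curation",
    "Hearing loss",
    "Fatty acid oxidation disorders",
)

#: Toy reference genome declared in fixture VCF headers.
DEFAULT_CONTIGS: dict[str, int] = {"chr1": 1_000_000, "chr2": 800_000}

#: Per-base background variant rate for cohort fixtures (SNPs planted
#: outside all biomarker regions; ~0.02/kb gives a few dozen per sample).
DEFAULT_BACKGROUND_RATE = 2e-5


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedVariant:
    """Ground truth for one planted cohort variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    gene_symbol: Optional[str]
    control_carriers: tuple[str, ...]
    patient_carriers: tuple[str, ...]

    @property
    def status(self) -> str:
        if not self.control_carriers and self.patient_carriers:
            return "patient_only"
        if not self.patient_carriers and self.control_carriers:
            return "control_only"
        return "shared"


@dataclass(frozen=True)
class PlantedDE:
    """Ground truth for one planted DE-table row."""

    gene_symbol: str
    log2fc: float
    padj: float
    expected_class: str


@dataclass
class FixtureManifest:
    """Machine-readable ground truth for a generated fixture."""

    seed: int
    regions: list[GeneRegion] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    background_variants: list[dict] = field(default_factory=list)
    planted_de: list[PlantedDE] = field(default_factory=list)
    thresholds: Optional[ThresholdConfig] = None
    n_controls: int = 0
    n_patients: int = 0
    control_samples: list[str] = field(default_factory=list)
    patient_samples: list[str] = field(default_factory=list)
    expression_panel: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "regions": [asdict(r) for r in self.regions],
            "planted_variants": [
                {**asdict(v), "status": v.status} for v in self.planted_variants
            ],
            "background_variants": self.background_variants,
            "planted_de": [asdict(d) for d in self.planted_de],
            "thresholds": asdict(self.thresholds) if self.thresholds else None,
            "n_controls": self.n_controls,
            "n_patients": self.n_patients,
            "control_samples": self.control_samples,
            "patient_samples": self.patient_samples,
            "expression_panel": self.expression_panel,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        return path


# ---------------------------------------------------------------------------
# Catalog fixture
# ---------------------------------------------------------------------------


def build_catalog_fixture() -> BiomarkerCatalog:
    """The in-memory mini-catalog: curated ALS gene--subtype assignments plus
    one synthetic placeholder record per remaining syndrome label.

    Placeholder records exist only so every syndrome label appears in the
    catalog; their gene symbols are clearly synthetic (``PANELGENE*``).
    """
    records: list[BiomarkerRecord] = []
    for gene, subtype in ALS_BIOMARKERS:
        label = "all ALS types" if subtype == ALL_SUBTYPES else f"ALS {subtype}"
        records.append(
            BiomarkerRecord(
                gene_symbol=gene,
                syndrome=ALS,
                subtype=subtype,
                category="neurological",
                moi="unknown",
                classification="curated",
                description=f"ALS biomarker ({label})",
                transcripts=(),
                report_url="",
            )
        )
    placeholder_id = 0
    for category, syndromes in (
        ("neurological", NEUROLOGICAL_SYNDROMES),
        ("non_neurological", NON_NEUROLOGICAL_SYNDROMES),
    ):
        for syndrome in syndromes:
            if syndrome == ALS:
                continue
            placeholder_id += 1
            records.append(
                BiomarkerRecord(
                    gene_symbol=f"PANELGENE{placeholder_id:02d}",
                    syndrome=syndrome,
                    subtype=ALL_SUBTYPES,
                    category=category,
                    moi="unknown",
                    classification="placeholder",
                    description=f"synthetic placeholder record for {syndrome}",
                    transcripts=(),
                    report_url="",
                )
            )
    return BiomarkerCatalog(records=records, source_label="fixture")


def make_catalog_fixture(path: str | Path) -> tuple[Path, BiomarkerCatalog]:
    """Write the mini-catalog TSV to ``path`` and return (path, catalog)."""
    catalog = build_catalog_fixture()
    out = save_catalog(catalog, path)
    return out, catalog


# ---------------------------------------------------------------------------
# Expression fixture
# ---------------------------------------------------------------------------


def make_expression_fixture(
    n_genes: int,
    de_spec: Sequence[tuple[str, float, float]],
    seed: int,
    out_path: str | Path,
    thresholds: ThresholdConfig | None = None,
    ensure_genes: Iterable[str] = (),
) -> tuple[Path, FixtureManifest]:
    """Write a synthetic DE CSV (columns ``symbol, log2FC, padj``).

    ``de_spec`` rows (gene, log2fc, padj) are written exactly as given; all
    other genes draw log2fc ~ Normal(0, 0.5) and padj ~ Uniform(0.2, 1), so
    they are NOT_SIGNIFICANT under any padj_max <= 0.2.  ``ensure_genes``
    are background-drawn genes guaranteed to appear in the table (e.g. a
    biomarker panel).  Output is deterministic under ``seed``.
    """
    thresholds = thresholds or ThresholdConfig()
    planted = {g.upper(): (float(l), float(p)) for g, l, p in de_spec}
    if len(planted) != len(de_spec):
        raise ValueError("de_spec contains a duplicated gene symbol")
    ensured = [g.upper() for g in ensure_genes if g.upper() not in planted]
    universe = list(planted) + ensured
    n_background = n_genes - len(universe)
    if n_background < 0:
        raise ValueError(
            f"n_genes={n_genes} smaller than the {len(universe)} named genes"
        )
    universe += [f"GENE{i:05d}" for i in range(1, n_background + 1)]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    rows = []
    manifest_de = []
    for idx in order:
        gene = universe[idx]
        if gene in planted:
            lfc, padj = planted[gene]
        else:
            lfc = float(rng.normal(0.0, 0.5))
            padj = float(rng.uniform(0.2, 1.0))
        rows.append((gene, lfc, padj))
        rec = ExpressionRecord(gene_symbol=gene, log2fc=lfc, padj=padj)
        manifest_de.append(
            PlantedDE(
                gene_symbol=gene,
                log2fc=lfc,
                padj=padj,
                expected_class=classify_expression(rec, thresholds).value,
            )
        )

    out_path = Path(out_path)
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["symbol", "log2FC", "padj"])
        for gene, lfc, padj in rows:
            writer.writerow([gene, f"{lfc:.6g}", f"{padj:.6g}"])

    manifest = FixtureManifest(
        seed=seed,
        planted_de=manifest_de,
        thresholds=thresholds,
        expression_panel=sorted(set(planted) | set(ensured)),
    )
    return out_path, manifest


# ---------------------------------------------------------------------------
# Cohort (VCF) fixture
# ---------------------------------------------------------------------------

_VCF_HEADER_TMPL = """##fileformat=VCFv4.2
##source=neurovar-fixtures
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _write_single_sample_vcf(
    path: Path,
    sample: str,
    records: Sequence[tuple[str, int, str, str, str]],
    contigs: dict[str, int],
) -> None:
    contig_lines = "".join(
        f"##contig=<ID={name},length={length}>\n" for name, length in contigs.items()
    )
    chrom_order = {name: i for i, name in enumerate(contigs)}
    body = sorted(records, key=lambda r: (chrom_order.get(r[0], 99), r[1], r[3]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER_TMPL.format(contigs=contig_lines, sample=sample))
        for chrom, pos, ref, alt, gt in body:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def _validate_plant_spec(
    plant_spec: Sequence[PlantedVariant],
    regions: Sequence[GeneRegion],
    n_controls: int,
    n_patients: int,
    contigs: dict[str, int],
    control_samples: Sequence[str],
    patient_samples: Sequence[str],
) -> None:
    by_gene = {r.gene_symbol: r for r in regions}
    for pv in plant_spec:
        if pv.chrom not in contigs or not (1 <= pv.pos <= contigs[pv.chrom]):
            raise ValueError(f"planted position outside contigs: {pv.chrom}:{pv.pos}")
        if classify_variant(pv.ref, pv.alt).value != pv.vclass:
            raise ValueError(
                f"declared class {pv.vclass} inconsistent with alleles "
                f"{pv.ref}>{pv.alt} at {pv.chrom}:{pv.pos}"
            )
        unknown = (set(pv.control_carriers) - set(control_samples)) | (
            set(pv.patient_carriers) - set(patient_samples)
        )
        if unknown:
            raise ValueError(f"unknown carrier sample id(s) {sorted(unknown)}")
        if pv.gene_symbol is not None:
            reg = by_gene.get(pv.gene_symbol)
            if reg is None:
                raise ValueError(f"planted gene {pv.gene_symbol} has no region")
            if pv.chrom != reg.chrom or not (reg.start <= pv.pos <= reg.end):
                raise ValueError(
                    f"planted variant {pv.chrom}:{pv.pos} outside its "
                    f"{pv.gene_symbol} region {reg.chrom}:{reg.start}-{reg.end}"
                )
        else:
            for reg in regions:
                if pv.chrom == reg.chrom and reg.start <= pv.pos <= reg.end:
                    raise ValueError(
                        f"gene-less planted variant {pv.chrom}:{pv.pos} falls "
                        f"inside {reg.gene_symbol}"
                    )


def make_cohort_fixture(
    regions: Sequence[GeneRegion],
    plant_spec: Sequence[PlantedVariant],
    n_controls: int,
    n_patients: int,
    seed: int,
    root: str | Path,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    contigs: dict[str, int] | None = None,
) -> tuple[Path, FixtureManifest]:
    """Write ``controls/`` and ``patients/`` single-sample VCF cohorts.

    Planted variants appear with genotype ``0/1`` in exactly the carrier
    samples the spec names (non-carriers simply lack the record, as in
    per-sample call sets).  Background SNPs are scattered at
    ``background_rate`` per base, always *outside* every gene region, so
    they can never enter a biomarker comparison table.  Both the planted
    and background variants are recorded in the returned manifest.
    Deterministic under ``seed``.
    """
    if n_controls < 1 or n_patients < 1:
        raise ValueError("each cohort needs at least one sample (one VCF file)")
    contigs = dict(contigs or DEFAULT_CONTIGS)
    control_samples = [f"CTRL{i:02d}" for i in range(1, n_controls + 1)]
    patient_samples = [f"PAT{i:02d}" for i in range(1, n_patients + 1)]
    _validate_plant_spec(
        plant_spec, regions, n_controls, n_patients, contigs,
        control_samples, patient_samples,
    )

    root = Path(root)
    (root / "controls").mkdir(parents=True, exist_ok=True)
    (root / "patients").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    chrom_names = list(contigs)
    chrom_lengths = np.array([contigs[c] for c in chrom_names], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    genome_len = int(chrom_lengths.sum())
    taken = {(pv.chrom, pv.pos) for pv in plant_spec}

    def in_any_region(chrom: str, pos: int) -> bool:
        return any(
            r.chrom == chrom and r.start <= pos <= r.end for r in regions
        )

    bases = "ACGT"
    background: list[dict] = []
    per_sample: dict[str, list[tuple[str, int, str, str, str]]] = {
        s: [] for s in control_samples + patient_samples
    }

    for pv in plant_spec:
        for sample in list(pv.control_carriers) + list(pv.patient_carriers):
            per_sample[sample].append((pv.chrom, pv.pos, pv.ref, pv.alt, "0/1"))

    for sample in control_samples + patient_samples:
        n_bg = int(rng.poisson(background_rate * genome_len))
        placed = 0
        while placed < n_bg:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
            pos = int(rng.integers(1, contigs[chrom] + 1))
            if (chrom, pos) in taken or in_any_region(chrom, pos):
                continue
            ref = bases[int(rng.integers(4))]
            alt = bases[int(rng.integers(4))]
            if alt == ref:
                continue
            per_sample[sample].append((chrom, pos, ref, alt, "0/1"))
            background.append(
                {"sample": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
            )
            placed += 1

    for sample in control_samples:
        _write_single_sample_vcf(
            root / "controls" / f"{sample}.vcf", sample, per_sample[sample], contigs
        )
    for sample in patient_samples:
        _write_single_sample_vcf(
            root / "patients" / f"{sample}.vcf", sample, per_sample[sample], contigs
        )

    manifest = FixtureManifest(
        seed=seed,
        regions=list(regions),
        planted_variants=list(plant_spec),
        background_variants=background,
        n_controls=n_controls,
        n_patients=n_patients,
        control_samples=control_samples,
        patient_samples=patient_samples,
    )
    return root, manifest


# ---------------------------------------------------------------------------
# Random fixture specs (for property/recovery testing)
# ---------------------------------------------------------------------------


def default_gene_regions() -> list[GeneRegion]:
    """Toy gene intervals for the 10 catalogued ALS genes, spread over the
    two-chromosome fixture genome."""
    genes = [g for g, _ in ALS_BIOMARKERS]
    regions = []
    for i, gene in enumerate(sorted(genes)):
        chrom = "chr1" if i < 5 else "chr2"
        start = 50_000 + (i % 5) * 120_000
        regions.append(
            GeneRegion(gene_symbol=gene, chrom=chrom, start=start, end=start + 4_999)
        )
    return regions


def random_plant_spec(
    regions: Sequence[GeneRegion],
    n_controls: int,
    n_patients: int,
    seed: int,
    n_snps: int = 8,
    n_indels: int = 3,
) -> list[PlantedVariant]:
    """Draw a random planted-variant spec (SNPs and indels inside random
    gene regions, each with at least one carrier).  Deterministic by seed."""
    rng = np.random.default_rng(seed)
    control_samples = [f"CTRL{i:02d}" for i in range(1, n_controls + 1)]
    patient_samples = [f"PAT{i:02d}" for i in range(1, n_patients + 1)]
    bases = "ACGT"
    used: set[tuple[str, int]] = set()
    spec: list[PlantedVariant] = []
    for kind in ["SNP"] * n_snps + ["INDEL"] * n_indels:
        reg = regions[int(rng.integers(len(regions)))]
        while True:
            pos = int(rng.integers(reg.start, reg.end + 1))
            if (reg.chrom, pos) not in used:
                used.add((reg.chrom, pos))
                break
        ref = bases[int(rng.integers(4))]
        if kind == "SNP":
            alt = bases[int((bases.index(ref) + 1 + rng.integers(3)) % 4)]
        else:
            ins = "".join(bases[int(b)] for b in rng.integers(0, 4, size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                ref, alt = ref, ref + ins  # insertion
            else:
                ref, alt = ref + ins, ref  # deletion
        # at least one carrier overall; each sample carries with p=0.4
        while True:
            cc = tuple(s for s in control_samples if rng.random() < 0.4)
            pc = tuple(s for s in patient_samples if rng.random() < 0.4)
            if cc or pc:
                break
        spec.append(
            PlantedVariant(
                chrom=reg.chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                vclass=classify_variant(ref, alt).value,
                gene_symbol=reg.gene_symbol,
                control_carriers=cc,
                patient_carriers=pc,
            )
        )
    return spec


# ---------------------------------------------------------------------------
# Case-study-shape preset
# ---------------------------------------------------------------------------

#: The 7 biomarker genes that carry the preset's 23 planted SNPs.
CASE_STUDY_SNP_GENES = ("C9ORF72", "DAO", "ERBB4", "FIG4", "KIF5A", "TBK1", "TUBA4A")

#: SNP counts per gene in CASE_STUDY_SNP_GENES order (sums to 23).
CASE_STUDY_SNP_COUNTS = (4, 4, 4, 3, 3, 3, 2)

#: Panel size of the emulated ALS biomarker expression panel.
CASE_STUDY_PANEL_SIZE = 21

#: Thresholds used in the emulated cohort analysis.
CASE_STUDY_THRESHOLDS = ThresholdConfig(padj_max=0.05, lfc_min=2.0)


def case_study_panel() -> list[str]:
    """The 21-gene ALS biomarker expression panel: the 10 catalogued genes
    plus clearly synthetic padding symbols (``ALSBM11``..``ALSBM21``)."""
    genes = sorted(g for g, _ in ALS_BIOMARKERS)
    genes += [f"ALSBM{i}" for i in range(11, CASE_STUDY_PANEL_SIZE + 1)]
    return genes


def make_case_study_fixture(
    out_dir: str | Path,
    seed: int,
    n_genes: int = 20_000,
    n_controls: int = 3,
    n_patients: int = 4,
) -> dict:
    """Emit the full case-study-shape fixture tree.

    Writes ``catalog.tsv``, ``regions.bed``, ``expression.csv``,
    ``panel.txt``, ``cohort/{controls,patients}/*.vcf`` and
    ``manifest.json`` under ``out_dir``.  Ground truth: exactly one of the
    21 panel genes (TUBA4A, log2fc 3.1, padj 0.004) is differentially
    expressed at thresholds (padj < 0.05, |log2fc| >= 2), and 23 SNPs /
    0 indels are planted across the 7 SNP-bearing biomarker genes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    catalog_path, catalog = make_catalog_fixture(out_dir / "catalog.tsv")

    regions = default_gene_regions()
    bed_path = out_dir / "regions.bed"
    with open(bed_path, "w", encoding="utf-8") as fh:
        for reg in regions:
            fh.write(f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\t{reg.gene_symbol}\n")

    # expression: 1 planted DE gene among a 21-gene biomarker panel, plus
    # explicit clearly-non-significant rows for the mutation-carrying genes
    panel = case_study_panel()
    de_spec = [
        ("TUBA4A", 3.1, 0.004),
        ("FUS", 0.6, 0.41),
        ("TARDBP", -0.3, 0.77),
        ("SOD1", 0.1, 0.93),
    ]
    expr_path, expr_manifest = make_expression_fixture(
        n_genes=n_genes,
        de_spec=de_spec,
        seed=int(rng.integers(2**31)),
        out_path=out_dir / "expression.csv",
        thresholds=CASE_STUDY_THRESHOLDS,
        ensure_genes=panel,
    )
    (out_dir / "panel.txt").write_text("\n".join(panel) + "\n", encoding="utf-8")

    # variants: 23 SNPs over 7 genes, no indels, each with >= 1 carrier
    control_samples = [f"CTRL{i:02d}" for i in range(1, n_controls + 1)]
    patient_samples = [f"PAT{i:02d}" for i in range(1, n_patients + 1)]
    by_gene = {r.gene_symbol: r for r in regions}
    bases = "ACGT"
    used: set[tuple[str, int]] = set()
    plant: list[PlantedVariant] = []
    for gene, count in zip(CASE_STUDY_SNP_GENES, CASE_STUDY_SNP_COUNTS):
        reg = by_gene[gene]
        for _ in range(count):
            while True:
                pos = int(rng.integers(reg.start, reg.end + 1))
                if (reg.chrom, pos) not in used:
                    used.add((reg.chrom, pos))
                    break
            ref = bases[int(rng.integers(4))]
            alt = bases[int((bases.index(ref) + 1 + rng.integers(3)) % 4)]
            # patients always contribute; controls sometimes share the variant
            while True:
                pc = tuple(s for s in patient_samples if rng.random() < 0.5)
                if pc:
                    break
            cc = tuple(s for s in control_samples if rng.random() < 0.2)
            plant.append(
                PlantedVariant(
                    chrom=reg.chrom, pos=pos, ref=ref, alt=alt, vclass="SNP",
                    gene_symbol=gene, control_carriers=cc, patient_carriers=pc,
                )
            )

    cohort_root, cohort_manifest = make_cohort_fixture(
        regions=regions,
        plant_spec=plant,
        n_controls=n_controls,
        n_patients=n_patients,
        seed=int(rng.integers(2**31)),
        root=out_dir / "cohort",
    )

    manifest = FixtureManifest(
        seed=seed,
        regions=regions,
        planted_variants=plant,
        background_variants=cohort_manifest.background_variants,
        planted_de=expr_manifest.planted_de,
        thresholds=CASE_STUDY_THRESHOLDS,
        n_controls=n_controls,
        n_patients=n_patients,
        control_samples=control_samples,
        patient_samples=patient_samples,
        expression_panel=panel,
    )
    manifest_path = manifest.save(out_dir / "manifest.json")

    return {
        "catalog": catalog_path,
        "regions": bed_path,
        "expression": expr_path,
        "panel": out_dir / "panel.txt",
        "cohort": cohort_root,
        "manifest": manifest_path,
        "manifest_obj": manifest,
    }
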