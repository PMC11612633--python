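"""Patients-vs-controls variant comparison at biomarker-gene sites.

Reads a directory of VCF cohorts laid out as ``ROOT/controls/*.vcf[.gz]``
and ``ROOT/patients/*.vcf[.gz]``, splits multi-allelic records into
biallelic variants, classifies each as SNP / INDEL / OTHER from its REF and
ALT alleles, assigns variants to genes by coordinate lookup against BED
regions, and builds the comparison table of carrier counts in each cohort.

Conventions
-----------
* VCF positions are 1-based; BED input is 0-based half-open and converted to
  1-based inclusive :class:`GeneRegion` intervals on load.
* A sample *carries* a variant when its genotype contains at least one copy
  of that alternate allele (het or hom); a fully missing genotype (``./.``)
  counts toward the cohort total but not toward carriers.
* Indel alleles are taken as written — no left-alignment or normalisation
  pass is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

_BASES = frozenset("ACGT")
_SEQ_RE = re.compile(r"^[ACGTN]+$")


class VariantClass(str, Enum):
    """Variant class derived from the REF/ALT allele pair."""

    SNP = "SNP"
    INDEL = "INDEL"
    OTHER = "OTHER"


class Carriage(str, Enum):
    """One sample's carriage state at one site."""

    CARRIES = "carries"
    DOES_NOT_CARRY = "does_not_carry"
    MISSING = "missing"


class CohortLayoutError(ValueError):
    """Raised when the cohort directory or a VCF inside it is malformed."""


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic interval, 1-based inclusive coordinates."""

    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start > self.end:
            raise ValueError(
                f"start must be <= end: {self.gene_symbol} {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class VariantRecord:
    """One normalised biallelic site with per-sample carriage."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: VariantClass
    gene_symbol: Optional[str] = None
    carriers: dict[str, Carriage] = field(default_factory=dict)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CohortComparisonRow:
    """One output row comparing the reference allele and the two cohorts."""

    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass
    control_carriers: int
    control_total: int
    patient_carriers: int
    patient_total: int
    status: str  # patient_only | control_only | shared

    def __post_init__(self) -> None:
        if not (0 <= self.control_carriers <= self.control_total):
            raise ValueError("control carrier count outside [0, total]")
        if not (0 <= self.patient_carriers <= self.patient_total):
            raise ValueError("patient carrier count outside [0, total]")


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a biallelic REF/ALT pair.

    SNP: both alleles a single base in {A, C, G, T}.  INDEL: plain-sequence
    alleles of unequal length.  OTHER: symbolic/breakend alleles, equal-length
    multi-base substitutions (MNPs), and N-containing single-base pairs.
    """
    if not ref or not alt:
        raise ValueError("REF and ALT must be nonempty")
    if ref == alt:
        raise ValueError(f"REF and ALT are identical: {ref!r}")
    ref_u, alt_u = ref.upper(), alt.upper()
    # symbolic ALTs (<DEL>, <INS>, ...), breakends, and spanning deletions
    if not _SEQ_RE.match(alt_u) or not _SEQ_RE.match(ref_u):
        return VariantClass.OTHER
    if len(ref_u) == 1 and len(alt_u) == 1:
        if ref_u in _BASES and alt_u in _BASES:
            return VariantClass.SNP
        return VariantClass.OTHER
    if len(ref_u) != len(alt_u):
        return VariantClass.INDEL
    return VariantClass.OTHER


def load_regions_bed(path: str | Path) -> list[GeneRegion]:
    """Load gene regions from a BED4 file (chrom, start, end, gene_symbol).

    BED coordinates are 0-based half-open; the returned regions are 1-based
    inclusive.  Comment/track/blank lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"regions BED not found: {path}")
    regions: list[GeneRegion] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path} line {lineno}: expected >= 4 BED columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            regions.append(
                GeneRegion(gene_symbol=name.upper(), chrom=chrom, start=start + 1, end=end)
            )
    return regions


class GeneRegionIndex:
    """Interval index over gene regions for O(log n) point lookups."""

    def __init__(self, regions: Iterable[GeneRegion]):
        self._trees: dict[str, IntervalTree] = {}
        for reg in regions:
            tree = self._trees.setdefault(reg.chrom, IntervalTree())
            # IntervalTree is half-open; region end is inclusive
            tree.addi(reg.start, reg.end + 1, reg)

    def lookup(self, chrom: str, pos: int) -> Optional[GeneRegion]:
        """Smallest region containing ``pos``; gene-symbol order breaks ties."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return None
        return min(hits, key=lambda r: (r.length, r.gene_symbol))


def assign_gene(
    v: VariantRecord, regions: Union[Sequence[GeneRegion], GeneRegionIndex]
) -> Optional[str]:
    """Gene whose interval contains ``v.pos`` on ``v.chrom``, or None.

    With nested/overlapping intervals the smallest wins, then the
    lexicographically first gene symbol.
    """
    index = regions if isinstance(regions, GeneRegionIndex) else GeneRegionIndex(regions)
    hit = index.lookup(v.chrom, v.pos)
    return hit.gene_symbol if hit else None


Cohort = dict[str, list[VariantRecord]]


def _read_vcf_file(path: Path, gene_tag: Optional[str]) -> tuple[list[str], list[VariantRecord]]:
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions for bad files
        raise CohortLayoutError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise CohortLayoutError(f"{path}: VCF has no sample columns")
    records: list[VariantRecord] = []
    try:
        for var in vcf:
            alts = var.ALT or []
            genotypes = var.genotypes  # [[a, b, phased], ...] per sample
            gene = None
            if gene_tag:
                tagged = var.INFO.get(gene_tag)
                if tagged:
                    gene = str(tagged).split("|")[0].upper()
            for alt_idx, alt in enumerate(alts, start=1):
                carriers: dict[str, Carriage] = {}
                for sample, gt in zip(samples, genotypes):
                    alleles = [a for a in gt[:-1]]  # last element is phasing flag
                    if alt_idx in alleles:
                        carriers[sample] = Carriage.CARRIES
                    elif all(a < 0 for a in alleles):
                        carriers[sample] = Carriage.MISSING
                    else:
                        carriers[sample] = Carriage.DOES_NOT_CARRY
                records.append(
                    VariantRecord(
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        vclass=classify_variant(var.REF, alt),
                        gene_symbol=gene,
                        carriers=carriers,
                    )
                )
    except CohortLayoutError:
        raise
    except Exception as exc:
        raise CohortLayoutError(f"malformed record in {path}: {exc}") from exc
    return samples, records


def _read_cohort_subdir(subdir: Path, gene_tag: Optional[str]) -> Cohort:
    vcfs = sorted(
        p for p in subdir.iterdir() if p.name.endswith((".vcf", ".vcf.gz"))
    )
    if not vcfs:
        raise CohortLayoutError(f"{subdir}: no VCF files (*.vcf or *.vcf.gz)")
    cohort: Cohort = {}
    for path in vcfs:
        samples, records = _read_vcf_file(path, gene_tag)
        for sample in samples:
            if sample in cohort:
                raise CohortLayoutError(
                    f"duplicate sample name {sample!r} (second occurrence in {path})"
                )
            cohort[sample] = records
    return cohort


def read_cohort_dir(
    root: str | Path, gene_tag: Optional[str] = None
) -> tuple[Cohort, Cohort]:
    """Read the ``controls/`` and ``patients/`` VCF cohorts under ``root``.

    Returns two maps sample -> list of biallelic :class:`VariantRecord`
    (multi-allelic records are split; symbolic ALTs become class OTHER).
    When ``gene_tag`` names an INFO tag (e.g. ``"GENE"``), pre-annotated
    gene symbols are read from it; otherwise genes are assigned later by
    coordinate lookup.

    Raises :class:`CohortLayoutError` for a missing subfolder, an empty or
    unparseable VCF, or a sample name repeated across files.
    """
    root = Path(root)
    missing = [name for name in ("controls", "patients") if not (root / name).is_dir()]
    if missing:
        raise CohortLayoutError(
            f"{root}: missing subfolder(s) {missing}; expected layout "
            f"ROOT/controls/*.vcf and ROOT/patients/*.vcf"
        )
    controls = _read_cohort_subdir(root / "controls", gene_tag)
    patients = _read_cohort_subdir(root / "patients", gene_tag)
    dup = set(controls) & set(patients)
    if dup:
        raise CohortLayoutError(f"sample name(s) in both cohorts: {sorted(dup)}")
    return controls, patients


def _carriage_by_site(cohort: Cohort) -> dict[tuple, dict[str, Carriage]]:
    sites: dict[tuple, dict[str, Carriage]] = {}
    for sample, records in cohort.items():
        for rec in records:
            entry = sites.setdefault(rec.site_key, {})
            if sample in rec.carriers:
                entry[sample] = rec.carriers[sample]
    return sites


def build_cohort_table(
    controls: Cohort,
    patients: Cohort,
    regions: Sequence[GeneRegion],
    genes: Iterable[str],
    vtype: Union[str, VariantClass],
) -> list[CohortComparisonRow]:
    """Build the reference/controls/patients comparison table.

    One row per distinct (chrom, pos, ref, alt) whose class equals ``vtype``
    (SNP or INDEL), whose position falls in a region of a gene in ``genes``,
    and which has at least one carrier in either cohort.  A sample whose VCF
    lacks a site counts as a non-carrier; a fully missing genotype counts
    toward the total but never toward carriers.  Rows are ordered by
    (gene_symbol, chrom, pos, alt).
    """
    vtype = VariantClass(vtype.upper() if isinstance(vtype, str) else vtype)
    if vtype not in (VariantClass.SNP, VariantClass.INDEL):
        raise ValueError(f"vtype must be SNP or INDEL, got {vtype}")
    panel = {g.upper() for g in genes}
    index = GeneRegionIndex(regions)

    # canonical VariantRecord per site (for class + any pre-annotated gene)
    site_meta: dict[tuple, VariantRecord] = {}
    for cohort in (controls, patients):
        for records in cohort.values():
            for rec in records:
                site_meta.setdefault(rec.site_key, rec)

    control_sites = _carriage_by_site(controls)
    patient_sites = _carriage_by_site(patients)

    rows: list[CohortComparisonRow] = []
    for key, rec in site_meta.items():
        if rec.vclass != vtype:
            continue
        gene = rec.gene_symbol or assign_gene(rec, index)
        if gene is None or gene.upper() not in panel:
            continue
        cc = sum(
            1 for c in control_sites.get(key, {}).values() if c is Carriage.CARRIES
        )
        pc = sum(
            1 for c in patient_sites.get(key, {}).values() if c is Carriage.CARRIES
        )
        if cc == 0 and pc == 0:
            continue
        if cc == 0:
            status = "patient_only"
        elif pc == 0:
            status = "control_only"
        else:
            status = "shared"
        rows.append(
            CohortComparisonRow(
                gene_symbol=gene.upper(),
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                vclass=rec.vclass,
                control_carriers=cc,
                control_total=len(controls),
                patient_carriers=pc,
                patient_total=len(patients),
                status=status,
            )
        )
    rows.sort(key=lambda r: (r.gene_symbol, r.chrom, r.pos, r.alt))
    return rows


def variant_report(table: Sequence[CohortComparisonRow]) -> dict:
    """Summary of a comparison table: total variants, distinct genes, and
    per-gene variant counts."""
    per_gene: dict[str, int] = {}
    for row in table:
        per_gene[row.gene_symbol] = per_gene.get(row.gene_symbol, 0) + 1
    return {
        "n_variants": len(table),
        "n_genes": len(per_gene),
        "per_gene": dict(sorted(per_gene.items())),
    }


def table_to_dataframe(table: Sequence[CohortComparisonRow]) -> pd.DataFrame:
    """Comparison table as a DataFrame with the canonical column order."""
    cols = [
        "gene_symbol", "chrom", "pos", "ref", "alt", "vclass",
        "control_carriers", "control_total",
        "patient_carriers", "patient_total", "status",
    ]
    return pd.DataFrame(
        [
            {
                "gene_symbol": r.gene_symbol,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "vclass": r.vclass.value,
                "control_carriers": r.control_carriers,
                "control_total": r.control_total,
                "patient_carriers": r.patient_carriers,
                "patient_total": r.patient_total,
                "status": r.status,
            }
            for r in table
        ],
        columns=cols,
    )
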