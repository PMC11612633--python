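"""Gene--disease-validity catalog: loading, saving, and panel queries.

The catalog holds one record per curated gene--syndrome--subtype assertion
(ClinGen gene-validity style).  A record whose subtype is the sentinel
``"all"`` asserts the gene for every subtype of its syndrome.  All gene
symbols are normalised to uppercase on load and matching is case-insensitive
thereafter.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

#: Sentinel subtype meaning "this gene applies to every subtype of the syndrome".
ALL_SUBTYPES = "all"

#: Disease-category labels.
CATEGORIES = ("neurological", "non_neurological")

#: Catalog file column order (TSV/CSV, header mandatory).
CATALOG_COLUMNS = (
    "gene_symbol",
    "syndrome",
    "subtype",
    "category",
    "moi",
    "classification",
    "description",
    "transcripts",
    "report_url",
)

MANDATORY_COLUMNS = ("gene_symbol", "syndrome", "subtype", "category")

#: Separator joining multiple transcript ids inside the ``transcripts`` field.
TRANSCRIPT_SEP = "|"


class CatalogError(ValueError):
    """Raised for malformed catalog files or invalid catalog queries."""


@dataclass(frozen=True)
class BiomarkerRecord:
    """One gene--disease-subtype validity assertion with provenance fields.

    Parameters
    ----------
    gene_symbol
        HGNC-style symbol, uppercase, no whitespace.
    syndrome
        Disease-syndrome label, e.g. ``"Amyotrophic lateral sclerosis"``.
    subtype
        Subtype label within the syndrome (e.g. ``"type 6"``) or the
        sentinel ``"all"``.
    category
        ``"neurological"`` or ``"non_neurological"``.
    moi
        Mode-of-inheritance token (AD, AR, XL, ...) or ``"unknown"``.
    classification
        Gene-validity classification label, e.g. ``"Definitive"``.
    description
        Free-text gene/disease description.
    transcripts
        Transcript identifiers (possibly empty).
    report_url
        URL of the online validity report (possibly empty).
    """

    gene_symbol: str
    syndrome: str
    subtype: str = ALL_SUBTYPES
    category: str = "neurological"
    moi: str = "unknown"
    classification: str = ""
    description: str = ""
    transcripts: tuple[str, ...] = ()
    report_url: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol or re.search(r"\s", self.gene_symbol):
            raise CatalogError(
                f"gene_symbol must be nonempty without whitespace: {self.gene_symbol!r}"
            )
        if not self.syndrome:
            raise CatalogError("syndrome must be nonempty")
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """Uniqueness key: (gene_symbol, syndrome, subtype)."""
        return (self.gene_symbol, self.syndrome, self.subtype)


@dataclass
class BiomarkerCatalog:
    """A collection of :class:`BiomarkerRecord` with a provenance label."""

    records: list[BiomarkerRecord] = field(default_factory=list)
    source_label: str = "fixture"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], int] = {}
        dups = []
        for i, rec in enumerate(self.records):
            if rec.key in seen:
                dups.append((rec.key, seen[rec.key], i))
            else:
                seen[rec.key] = i
        if dups:
            detail = "; ".join(
                f"{key} at records {a} and {b}" for key, a, b in dups
            )
            raise CatalogError(f"duplicate (gene, syndrome, subtype) keys: {detail}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _normalize_record(rec: BiomarkerRecord) -> BiomarkerRecord:
    return replace(rec, gene_symbol=rec.gene_symbol.upper())


def load_catalog(path: str | Path) -> BiomarkerCatalog:
    """Read a catalog from a tab- or comma-delimited file.

    The delimiter is sniffed from the header line (tab wins when both are
    present).  The mandatory columns are ``gene_symbol, syndrome, subtype,
    category``; the remaining :data:`CATALOG_COLUMNS` are optional and
    default to empty.  Transcript lists are split on ``"|"``.  Rows that
    violate record invariants, and duplicate (gene, syndrome, subtype) keys,
    abort the load with 1-based data-row numbers in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"catalog file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise CatalogError(f"{path}: empty file, expected a header row")
        delim = "\t" if "\t" in header_line else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        headers = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in headers]
        if missing:
            raise CatalogError(
                f"{path}: missing mandatory column(s) {missing}; found {headers}"
            )
        records: list[BiomarkerRecord] = []
        keys: dict[tuple[str, str, str], int] = {}
        errors: list[str] = []
        for rownum, row in enumerate(reader, start=1):
            try:
                transcripts = tuple(
                    t for t in (row.get("transcripts") or "").split(TRANSCRIPT_SEP) if t
                )
                rec = _normalize_record(
                    BiomarkerRecord(
                        gene_symbol=(row.get("gene_symbol") or "").strip(),
                        syndrome=(row.get("syndrome") or "").strip(),
                        subtype=(row.get("subtype") or ALL_SUBTYPES).strip() or ALL_SUBTYPES,
                        category=(row.get("category") or "").strip(),
                        moi=(row.get("moi") or "unknown").strip() or "unknown",
                        classification=(row.get("classification") or "").strip(),
                        description=(row.get("description") or "").strip(),
                        transcripts=transcripts,
                        report_url=(row.get("report_url") or "").strip(),
                    )
                )
            except CatalogError as exc:
                errors.append(f"row {rownum}: {exc}")
                continue
            if rec.key in keys:
                errors.append(
                    f"row {rownum}: duplicate key {rec.key} (first seen row {keys[rec.key]})"
                )
            else:
                keys[rec.key] = rownum
                records.append(rec)
        if errors:
            raise CatalogError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
    return BiomarkerCatalog(records=records, source_label=str(path))


def save_catalog(catalog: BiomarkerCatalog, path: str | Path) -> Path:
    """Write a catalog as a TSV with the canonical column order."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for rec in catalog.records:
            writer.writerow(
                [
                    rec.gene_symbol,
                    rec.syndrome,
                    rec.subtype,
                    rec.category,
                    rec.moi,
                    rec.classification,
                    rec.description,
                    TRANSCRIPT_SEP.join(rec.transcripts),
                    rec.report_url,
                ]
            )
    return path


def list_syndromes(
    catalog: BiomarkerCatalog, category: Optional[str] = None
) -> list[str]:
    """Distinct syndrome labels, lexicographically sorted.

    When ``category`` is given, only syndromes of that disease category are
    returned.
    """
    if category is not None and category not in CATEGORIES:
        raise CatalogError(f"unknown category {category!r}; choose from {CATEGORIES}")
    labels = {
        rec.syndrome
        for rec in catalog.records
        if category is None or rec.category == category
    }
    return sorted(labels)


def _subtype_sort_key(label: str) -> tuple:
    """Natural-numeric order so that 'type 2' < 'type 10'."""
    parts = re.split(r"(\d+)", label)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _require_syndrome(catalog: BiomarkerCatalog, syndrome: str) -> None:
    known = list_syndromes(catalog)
    if syndrome not in known:
        raise CatalogError(f"unknown syndrome {syndrome!r}; known syndromes: {known}")


def list_subtypes(catalog: BiomarkerCatalog, syndrome: str) -> list[str]:
    """Distinct subtype labels for a syndrome, natural-numerically sorted.

    The sentinel ``"all"`` is excluded: it is a wildcard, not a subtype.
    """
    _require_syndrome(catalog, syndrome)
    labels = {
        rec.subtype
        for rec in catalog.records
        if rec.syndrome == syndrome and rec.subtype != ALL_SUBTYPES
    }
    return sorted(labels, key=_subtype_sort_key)


def get_biomarkers(
    catalog: BiomarkerCatalog, syndrome: str, subtype: Optional[str] = None
) -> list[BiomarkerRecord]:
    """Biomarker records for a syndrome, optionally restricted to a subtype.

    With a subtype, records matching it are returned *plus* records carrying
    the ``"all"`` sentinel (genes asserted for every subtype).  Without one,
    all records for the syndrome are returned.  Ordered by gene symbol.
    """
    _require_syndrome(catalog, syndrome)
    if subtype is not None and subtype not in list_subtypes(catalog, syndrome):
        raise CatalogError(
            f"unknown subtype {subtype!r} for {syndrome!r}; "
            f"known subtypes: {list_subtypes(catalog, syndrome)}"
        )
    hits = [
        rec
        for rec in catalog.records
        if rec.syndrome == syndrome
        and (subtype is None or rec.subtype in (subtype, ALL_SUBTYPES))
    ]
    return sorted(hits, key=lambda r: r.gene_symbol)


def biomarker_gene_set(
    catalog: BiomarkerCatalog, syndrome: str, subtype: Optional[str] = None
) -> set[str]:
    """Distinct gene symbols of :func:`get_biomarkers` — the panel shared by
    the expression and variants stages."""
    return {rec.gene_symbol for rec in get_biomarkers(catalog, syndrome, subtype)}
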