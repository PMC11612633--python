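"""Differential-expression profiling of biomarker genes.

This module consumes a *precomputed* DE results table (gene symbol, log2
fold change, adjusted p-value — typically a DESeq2/edgeR export) and
classifies each gene as UP, DOWN or NOT_SIGNIFICANT against user thresholds.
It never computes fold changes or p-values itself.

Classification rule (inclusive fold-change boundary, strict p boundary):

* UP   iff padj is present, padj < padj_max and log2fc >= +lfc_min
* DOWN iff padj is present, padj < padj_max and log2fc <= -lfc_min
* NOT_SIGNIFICANT otherwise (including missing padj)
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Floor applied to padj before taking -log10, so padj = 0 plots finitely.
PADJ_FLOOR = 1e-300


class DEClass(str, Enum):
    """Differential-expression call for one gene."""

    UP = "UP"
    DOWN = "DOWN"
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs defining "differentially expressed".

    Parameters
    ----------
    padj_max
        Adjusted-p-value cutoff in (0, 1]; a gene is significant only when
        its padj is strictly below this. Default 0.01.
    lfc_min
        Non-negative |log2 fold change| cutoff; the boundary is inclusive.
        Default 2.0.
    """

    padj_max: float = 0.01
    lfc_min: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.padj_max <= 1.0):
            raise ValueError(f"padj_max must be in (0, 1], got {self.padj_max}")
        if self.lfc_min < 0.0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")


@dataclass
class ExpressionRecord:
    """One gene's DE result plus its assigned class."""

    gene_symbol: str
    log2fc: float
    padj: Optional[float]  # None = missing/NA
    de_class: DEClass = DEClass.NOT_SIGNIFICANT

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(
                f"padj must be in [0, 1] or missing, got {self.padj} for {self.gene_symbol}"
            )


@dataclass(frozen=True)
class VolcanoPoint:
    """One volcano-plot point: x = log2fc, y = -log10(padj)."""

    gene_symbol: str
    x: float
    y: float
    de_class: DEClass
    is_biomarker: bool


def classify_expression(rec: ExpressionRecord, thr: ThresholdConfig) -> DEClass:
    """Classify a record as UP / DOWN / NOT_SIGNIFICANT under ``thr``."""
    if rec.padj is None or not (rec.padj < thr.padj_max):
        return DEClass.NOT_SIGNIFICANT
    if rec.log2fc >= thr.lfc_min:
        return DEClass.UP
    if rec.log2fc <= -thr.lfc_min:
        return DEClass.DOWN
    return DEClass.NOT_SIGNIFICANT


def _parse_float(cell: str) -> Optional[float]:
    txt = (cell or "").strip()
    if txt == "" or txt.upper() in {"NA", "NAN", "NULL", "NONE"}:
        return None
    try:
        val = float(txt)
    except ValueError:
        return None
    if math.isnan(val):
        return None
    return val


def read_expression_table(
    path: str | Path,
    colmap: Mapping[str, str],
    delimiter: str = ",",
    strict: bool = False,
) -> list[ExpressionRecord]:
    """Read a DE results CSV into :class:`ExpressionRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row.
    colmap
        Maps the logical keys ``gene``, ``log2fc``, ``padj`` to the file's
        column names.
    delimiter
        Field delimiter (default comma).
    strict
        When True, rows with an unparseable log2fc abort the load; otherwise
        they are dropped with a logged warning.  Unparseable or NA padj
        always becomes missing padj.

    Gene symbols are uppercased; duplicate symbols keep the first occurrence
    (a warning reports the number dropped).  ``de_class`` is initialised to
    NOT_SIGNIFICANT; call :func:`classify_expression` to assign it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    for key in ("gene", "log2fc", "padj"):
        if key not in colmap:
            raise ValueError(f"colmap must map {key!r} to a column name")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        headers = reader.fieldnames
        if not headers:
            raise ValueError(f"{path}: empty file, expected a header row")
        absent = [c for c in colmap.values() if c not in headers]
        if absent:
            raise ValueError(
                f"{path}: column(s) {absent} not in header; available: {headers}"
            )
        records: list[ExpressionRecord] = []
        seen: set[str] = set()
        n_dup = 0
        n_bad = 0
        for rownum, row in enumerate(reader, start=1):
            gene = (row[colmap["gene"]] or "").strip().upper()
            lfc = _parse_float(row[colmap["log2fc"]])
            padj = _parse_float(row[colmap["padj"]])
            if not gene or lfc is None:
                if strict:
                    raise ValueError(
                        f"{path} row {rownum}: unparseable gene/log2fc "
                        f"({row[colmap['gene']]!r}, {row[colmap['log2fc']]!r})"
                    )
                n_bad += 1
                continue
            if padj is not None and not (0.0 <= padj <= 1.0):
                if strict:
                    raise ValueError(f"{path} row {rownum}: padj {padj} outside [0, 1]")
                padj = None
            if gene in seen:
                n_dup += 1
                continue
            seen.add(gene)
            records.append(ExpressionRecord(gene_symbol=gene, log2fc=lfc, padj=padj))
    if n_dup:
        logger.warning("%s: dropped %d duplicate gene symbol row(s), first kept", path, n_dup)
    if n_bad:
        logger.warning("%s: dropped %d unparseable row(s)", path, n_bad)
    return records


def expression_summary(
    records: Sequence[ExpressionRecord],
    genes: Iterable[str],
    thr: ThresholdConfig,
) -> pd.DataFrame:
    """Per-biomarker summary table.

    One row per gene in ``genes`` (uppercased), ordered by symbol, with
    columns ``gene_symbol, log2fc, padj, de_class, in_input``.  Genes absent
    from ``records`` get ``in_input=False`` and NA value fields.
    """
    by_gene = {}
    for rec in records:
        by_gene.setdefault(rec.gene_symbol.upper(), rec)
    rows = []
    for gene in sorted({g.upper() for g in genes}):
        rec = by_gene.get(gene)
        if rec is None:
            rows.append(
                {
                    "gene_symbol": gene,
                    "log2fc": math.nan,
                    "padj": math.nan,
                    "de_class": "",
                    "in_input": False,
                }
            )
        else:
            rows.append(
                {
                    "gene_symbol": gene,
                    "log2fc": rec.log2fc,
                    "padj": math.nan if rec.padj is None else rec.padj,
                    "de_class": classify_expression(rec, thr).value,
                    "in_input": True,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_symbol", "log2fc", "padj", "de_class", "in_input"]
    )


def volcano_data(
    records: Sequence[ExpressionRecord],
    genes: Iterable[str],
    thr: ThresholdConfig,
) -> list[VolcanoPoint]:
    """Volcano-plot dataset: one point per record with a nonmissing padj.

    y is ``-log10(max(padj, 1e-300))`` so a reported padj of exactly zero
    still yields a finite coordinate.
    """
    panel = {g.upper() for g in genes}
    points = []
    for rec in records:
        if rec.padj is None:
            continue
        y = -math.log10(max(rec.padj, PADJ_FLOOR))
        points.append(
            VolcanoPoint(
                gene_symbol=rec.gene_symbol,
                x=rec.log2fc,
                y=y,
                de_class=classify_expression(rec, thr),
                is_biomarker=rec.gene_symbol.upper() in panel,
            )
        )
    return points


_CLASS_COLORS = {
    DEClass.UP: "#d62728",
    DEClass.DOWN: "#1f77b4",
    DEClass.NOT_SIGNIFICANT: "#bbbbbb",
}


def render_volcano(
    points: Sequence[VolcanoPoint],
    thr: ThresholdConfig,
    out: str | Path,
) -> Path:
    """Render the volcano plot to ``out`` (format from the extension).

    Threshold guide lines are drawn at x = ±lfc_min and y = -log10(padj_max);
    biomarker points are drawn larger, edged in black, and labelled.
    """
    if not points:
        raise ValueError("cannot render a volcano plot from zero points")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for cls in DEClass:
        xs = [p.x for p in points if p.de_class == cls and not p.is_biomarker]
        ys = [p.y for p in points if p.de_class == cls and not p.is_biomarker]
        if xs:
            ax.scatter(xs, ys, s=10, c=_CLASS_COLORS[cls], label=cls.value, alpha=0.6)
    bio = [p for p in points if p.is_biomarker]
    if bio:
        ax.scatter(
            [p.x for p in bio],
            [p.y for p in bio],
            s=45,
            c=[_CLASS_COLORS[p.de_class] for p in bio],
            edgecolors="black",
            linewidths=0.8,
            label="biomarker",
            zorder=3,
        )
        for p in bio:
            ax.annotate(p.gene_symbol, (p.x, p.y), fontsize=7,
                        textcoords="offset points", xytext=(3, 3))
    ax.axvline(thr.lfc_min, ls="--", lw=0.8, c="black")
    ax.axvline(-thr.lfc_min, ls="--", lw=0.8, c="black")
    ax.axhline(-math.log10(thr.padj_max), ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p-value")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
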